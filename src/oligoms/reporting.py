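"""Tabular and graphical report output for search results."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .search import CoverageReport, SiteAssignment, SpectrumAssignment

__all__ = ["sites_to_frame", "write_reports", "plot_coverage"]


def sites_to_frame(sites: Sequence[SiteAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parent": s.parent_id,
                "position": s.position,
                "modification": s.modification,
                "fragment": s.fragment,
                "status": s.status,
                "window": s.window,
                "occurrences": ";".join(f"{a}-{b}" for a, b in s.occurrences),
                "spectra": ";".join(s.spectra),
            }
            for s in sites
        ]
    )


def assignments_to_frame(assignments: Sequence[SpectrumAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "run": a.spectrum.run_id,
                "scan": a.spectrum.scan_id,
                "fragment": a.candidate.oligo.notation(),
                "missed_cleavages": a.candidate.product.missed_cleavages,
                "precursor_ppm_error": a.match.precursor_ppm_error,
                "n_matched_ions": len(a.match.matched),
                "score": a.match.score,
                "localization": a.match.localization,
            }
            for a in assignments
        ]
    )


def write_reports(
    sites: Sequence[SiteAssignment],
    coverage: CoverageReport,
    assignments: Sequence[SpectrumAssignment],
    outdir,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites_to_frame(sites).to_csv(outdir / "ptm_table.tsv", sep="\t", index=False)
    coverage.to_frame().to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    assignments_to_frame(assignments).to_csv(outdir / "assignments.tsv", sep="\t", index=False)


def plot_coverage(coverage: CoverageReport, path) -> None:
    """One-row coverage map: covered positions dark, gaps light."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 1.2))
    ax.imshow(
        coverage.covered[None, :],
        aspect="auto",
        cmap="Greys",
        interpolation="nearest",
        vmin=0,
        vmax=1,
    )
    ax.set_yticks([])
    ax.set_xlabel("position (nt)")
    ax.set_title(
        f"{coverage.parent_id}: {100 * coverage.covered_fraction:.1f}% covered"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
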