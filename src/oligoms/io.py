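"""File-format boundaries: FASTA, MGF-like peak lists, YAML configs, BED.

The native peak-list format is standard MGF with two extra per-block
parameters: ``MSLEVEL`` (1 for survey scans, which carry no PEPMASS, 2 for
MS/MS) and a ``TITLE`` of the form ``run_id#scan_id``.  Charge states are
written negative-mode style (``CHARGE=2-``).  mzML files can be read
through a thin adapter when an mzML-capable pyteomics install is present.

Windows and guides are exported as BED (0-based, half-open — the only
place where coordinates leave the 1-based inclusive frame) plus a
plain-text guide list.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .chemistry import Modification, ModificationAlphabet
from .digestion import CleavageWindow, ParentRNA
from .spectra import SpectrumRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "alphabet_from_yaml",
    "alphabet_to_yaml",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "windows_to_bed",
    "guides_to_text",
    "write_truth",
    "read_truth",
    "write_dataset",
]


def read_fasta(path) -> List[ParentRNA]:
    """Parse RNA (or DNA; T is normalised to U) sequences."""
    return [
        ParentRNA(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(parents: Sequence[ParentRNA], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in parents
    ]
    SeqIO.write(records, str(path), "fasta")


def alphabet_to_yaml(alphabet: ModificationAlphabet, path) -> None:
    data = {
        "modifications": [
            {
                "name": m.name,
                "mass_delta": m.mass_delta,
                "allowed_bases": "".join(sorted(m.allowed_bases)),
                "blocks_t1_cleavage": m.blocks_t1_cleavage,
            }
            for m in alphabet
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def alphabet_from_yaml(path) -> ModificationAlphabet:
    data = yaml.safe_load(Path(path).read_text())
    return ModificationAlphabet(
        Modification(
            name=e["name"],
            mass_delta=float(e["mass_delta"]),
            allowed_bases=frozenset(e["allowed_bases"]),
            blocks_t1_cleavage=bool(e.get("blocks_t1_cleavage", False)),
        )
        for e in data["modifications"]
    )


def _record_to_mgf_dict(s: SpectrumRecord) -> dict:
    params = {
        "title": f"{s.run_id}#{s.scan_id}",
        "rtinseconds": s.retention,
        "mslevel": str(s.ms_level),
    }
    if s.ms_level == 2:
        params["pepmass"] = (s.precursor_mz, None)
        params["charge"] = [-int(s.precursor_charge)]
    return {
        "m/z array": s.peaks[:, 0] if len(s.peaks) else np.empty(0),
        "intensity array": s.peaks[:, 1] if len(s.peaks) else np.empty(0),
        "params": params,
    }


def write_mgf(spectra: Sequence[SpectrumRecord], path) -> None:
    _mgf.write([_record_to_mgf_dict(s) for s in spectra], str(path), file_mode="w")


def _mgf_dict_to_record(d: dict) -> SpectrumRecord:
    params = d["params"]
    title = params.get("title", "run#scan")
    run_id, _, scan_id = title.partition("#")
    ms_level = int(params.get("mslevel", 2))
    peaks = np.column_stack([d["m/z array"], d["intensity array"]]) if len(d["m/z array"]) else np.empty((0, 2))
    precursor_mz = None
    precursor_charge = None
    if ms_level == 2:
        precursor_mz = float(params["pepmass"][0])
        charge = params.get("charge")
        precursor_charge = abs(int(charge[0])) if charge else 1
    return SpectrumRecord(
        run_id=run_id,
        scan_id=scan_id or "0",
        retention=float(params.get("rtinseconds", 0.0)),
        peaks=peaks,
        ms_level=ms_level,
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
    )


def read_mgf(path) -> List[SpectrumRecord]:
    with _mgf.read(str(path), use_index=False) as reader:
        return [_mgf_dict_to_record(d) for d in reader]


def read_mzml(path, run_id: Optional[str] = None) -> List[SpectrumRecord]:
    """Thin mzML adapter (negative-mode centroided data assumed)."""
    from pyteomics import mzml as _mzml

    out = []
    rid = run_id or Path(path).stem
    with _mzml.read(str(path)) as reader:
        for i, sp in enumerate(reader):
            ms_level = int(sp.get("ms level", 1))
            precursor_mz = None
            precursor_charge = None
            if ms_level == 2:
                ion = sp["precursorList"]["precursor"][0]["selectedIonList"]["selectedIon"][0]
                precursor_mz = float(ion["selected ion m/z"])
                precursor_charge = abs(int(ion.get("charge state", 1)))
            rt = 0.0
            try:
                rt = float(sp["scanList"]["scan"][0]["scan start time"])
            except (KeyError, IndexError):
                pass
            out.append(
                SpectrumRecord(
                    run_id=rid,
                    scan_id=str(sp.get("id", i)),
                    retention=rt,
                    peaks=np.column_stack([sp["m/z array"], sp["intensity array"]]),
                    ms_level=ms_level,
                    precursor_mz=precursor_mz,
                    precursor_charge=precursor_charge,
                )
            )
    return out


def windows_to_bed(windows: Sequence[CleavageWindow], path) -> None:
    """BED6-lite export; 1-based inclusive -> 0-based half-open."""
    lines = [
        f"{w.parent_id}\t{w.start - 1}\t{w.end}\t{w.name}\n" for w in windows
    ]
    Path(path).write_text("".join(lines))


def guides_to_text(windows: Sequence[CleavageWindow], path) -> None:
    lines = []
    for w in windows:
        if w.guide:
            lines.append(f"{w.name}\t{w.guide}\n")
    Path(path).write_text("".join(lines))


def write_truth(truth: Dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth(path) -> Dict:
    return json.loads(Path(path).read_text())


def write_dataset(dataset, outdir) -> None:
    """Persist a simulated dataset: FASTA + per-condition MGF + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([dataset.parent], outdir / "parent.fasta")
    for condition, spectra in dataset.runs.items():
        write_mgf(spectra, outdir / f"{condition}.mgf")
    write_truth(dataset.truth, outdir / "truth.json")
    all_windows = []
    seen = set()
    for ws in dataset.windows.values():
        for w in ws:
            if (w.start, w.end) not in seen:
                seen.add((w.start, w.end))
                all_windows.append(CleavageWindow(w.parent_id, w.start, w.end, guide=w.guide))
    if all_windows:
        windows_to_bed(sorted(all_windows, key=lambda w: w.start), outdir / "windows.bed")
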