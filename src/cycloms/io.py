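"""Readers and writers for the plain-text formats the pipeline consumes.

* FASTA for peptide sequences and contigs (Biopython).  A cyclic peptide
  carries ``topology=cyclic`` in its description line; disulfides are
  encoded as ``disulfides=i-j,k-l``.
* MGF for MS/MS spectra (pyteomics).
* Two-column TSV peak lists (m/z, intensity).
* Plate CSVs: readings as ``well,time_min,rfu`` plus a layout table
  ``well,sample,concentration,role``.
* Pipeline configuration as YAML, round-tripping losslessly.

Parsing is strict: malformed records raise with the offending line; no
record is ever silently dropped.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .kinetics import KineticTrace
from .masses import PeptideSpecies
from .mining import Contig
from .msms import Spectrum

__all__ = [
    "PipelineConfig",
    "read_peptide_fasta",
    "write_peptide_fasta",
    "read_contig_fasta",
    "write_contig_fasta",
    "read_mgf",
    "write_mgf",
    "read_peak_list",
    "write_peak_list",
    "read_plate",
    "write_plate",
]


@dataclass
class PipelineConfig:
    """Tolerances, rules and seeds actually used by a pipeline run."""

    ms1_tol_da: float = 0.25
    ms2_tol_da: float = 0.3
    ms1_ppm: float | None = None  # ppm mode if set; overrides ms1_tol_da
    enzymes: list[str] = field(default_factory=lambda: ["trypsin", "gluc", "chymotrypsin"])
    alignment_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    min_score: float = 30.0
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if self.ms1_tol_da <= 0 or self.ms2_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        if self.ms1_ppm is not None and self.ms1_ppm <= 0:
            raise ValueError("ppm tolerance must be positive")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def ms1_tolerance_for(self, mz: float) -> float:
        """Absolute MS1 tolerance at a given m/z (Da or ppm mode)."""
        if self.ms1_ppm is not None:
            return mz * self.ms1_ppm * 1e-6
        return self.ms1_tol_da


def _describe(p: PeptideSpecies) -> str:
    parts = [f"topology={p.topology}"]
    if p.disulfide_bonds:
        parts.append(
            "disulfides=" + ",".join(f"{i}-{j}" for i, j in p.disulfide_bonds)
        )
    return " ".join(parts)


def write_peptide_fasta(species: list[PeptideSpecies], path, ids=None):
    records = []
    for k, p in enumerate(species):
        name = ids[k] if ids else f"peptide{k + 1}"
        records.append(SeqRecord(Seq(p.sequence), id=name, description=_describe(p)))
    SeqIO.write(records, str(path), "fasta")


def read_peptide_fasta(path) -> list[PeptideSpecies]:
    species = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topology = "cyclic" if "topology=cyclic" in rec.description else "linear"
        bonds = []
        for token in rec.description.split():
            if token.startswith("disulfides="):
                for pair in token.split("=", 1)[1].split(","):
                    i, j = pair.split("-")
                    bonds.append((int(i), int(j)))
        species.append(PeptideSpecies(str(rec.seq), topology, disulfide_bonds=bonds))
    return species


def write_contig_fasta(contigs: list[Contig], path):
    SeqIO.write(
        [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs],
        str(path),
        "fasta",
    )


def read_contig_fasta(path) -> list[Contig]:
    return [Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_mgf(spectra: dict[str, Spectrum], path):
    entries = []
    for title, s in spectra.items():
        entries.append(
            {
                "m/z array": [mz for mz, _ in s.peaks],
                "intensity array": [i for _, i in s.peaks],
                "params": {
                    "title": title,
                    "pepmass": s.precursor_mz,
                    "charge": s.precursor_charge,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> dict[str, Spectrum]:
    spectra = {}
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params.get("pepmass", (0.0,))
            charge = params.get("charge", [1])
            spectra[params.get("title", f"spectrum{len(spectra) + 1}")] = Spectrum(
                precursor_mz=float(pepmass[0]),
                precursor_charge=int(charge[0]),
                peaks=list(
                    zip(
                        (float(x) for x in entry["m/z array"]),
                        (float(x) for x in entry["intensity array"]),
                    )
                ),
            )
    return spectra


def write_peak_list(peaks: list[tuple[float, float]], path):
    pd.DataFrame(peaks, columns=["mz", "intensity"]).to_csv(
        str(path), sep="\t", index=False
    )


def read_peak_list(path) -> list[tuple[float, float]]:
    df = pd.read_csv(str(path), sep=r"\s+", engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"peak list {path} needs two columns (m/z, intensity)")
    return [(float(a), float(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_plate(traces: list[KineticTrace], readings_path, layout_path):
    rows = [
        {"well": t.well, "time_min": tt, "rfu": rr}
        for t in traces
        for tt, rr in zip(t.times, t.rfu)
    ]
    pd.DataFrame(rows).to_csv(str(readings_path), index=False)
    layout = [
        {
            "well": t.well,
            "sample": t.sample,
            "concentration": t.concentration,
            "role": (
                t.sample
                if t.sample in ("substrate_control", "max_activity")
                else "sample"
            ),
        }
        for t in traces
    ]
    pd.DataFrame(layout).to_csv(str(layout_path), index=False)


def read_plate(readings_path, layout_path) -> list[KineticTrace]:
    readings = pd.read_csv(str(readings_path))
    layout = pd.read_csv(str(layout_path)).set_index("well")
    traces = []
    for well, group in readings.groupby("well", sort=False):
        group = group.sort_values("time_min")
        if well not in layout.index:
            raise ValueError(f"well {well!r} missing from layout")
        meta = layout.loc[well]
        traces.append(
            KineticTrace(
                well=str(well),
                sample=str(meta["sample"]),
                concentration=float(meta["concentration"]),
                times=list(group["time_min"]),
                rfu=list(group["rfu"]),
            )
        )
    return traces
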