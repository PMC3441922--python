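"""File formats and run configuration.

All tabular formats are plain TSV with a header row; codon coordinates in
files are 1-based inclusive.  FASTA handling goes through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import CodonAlignment
from .errors import OverlapError, ParseError, RangeError
from .trees import PhyloTree, read_tree  # noqa: F401  (re-exported)

STRUCTURAL_CLASSES = {"P", "L", "S", "helixA", "helixB", "coil", "E", "E+", "DYW", "other"}
EDITING_STATES = {"EDITED_C", "GENOMIC_T", "UNEDITED_C"}
BELOW_10 = "<10"


# ---------------------------------------------------------------------------
# codon alignments


def read_codon_alignment(path, allow_stop_codons: bool = False) -> CodonAlignment:
    """Read an aligned in-frame FASTA file.

    Raises FrameError / AlignmentError / StopCodonError on invalid input
    (see :class:`~pprsel.alignment.CodonAlignment`).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    seqs = {r.id: str(r.seq).upper() for r in records}
    return CodonAlignment(taxa, seqs, allow_stop_codons=allow_stop_codons)


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    records = [SeqRecord(Seq(aln.sequences[t]), id=t, description="") for t in aln.taxa]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# partition maps


@dataclass
class PartitionEntry:
    name: str
    structural_class: str
    start_codon: int  # 1-based inclusive
    end_codon: int

    def __post_init__(self):
        if self.structural_class not in STRUCTURAL_CLASSES:
            raise ValueError(f"unknown structural class {self.structural_class!r}")
        if not (1 <= self.start_codon <= self.end_codon):
            raise RangeError(
                f"bad codon range {self.start_codon}..{self.end_codon} for {self.name!r}"
            )

    @property
    def n_codons(self) -> int:
        return self.end_codon - self.start_codon + 1

    def columns(self) -> list[int]:
        return list(range(self.start_codon, self.end_codon + 1))


@dataclass
class PartitionMap:
    """Named codon-range partitions with structural classes."""

    entries: list[PartitionEntry] = field(default_factory=list)

    def __post_init__(self):
        by_name: dict[str, list[PartitionEntry]] = {}
        for e in self.entries:
            by_name.setdefault(e.name, []).append(e)
        for name, group in by_name.items():
            spans = sorted((e.start_codon, e.end_codon) for e in group)
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise OverlapError(f"overlapping ranges for partition {name!r}")

    @property
    def names(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.name)
        return list(seen)

    @property
    def classes(self) -> list[str]:
        return sorted({e.structural_class for e in self.entries})

    def by_name(self, name: str) -> list[PartitionEntry]:
        got = [e for e in self.entries if e.name == name]
        if not got:
            raise KeyError(f"no partition named {name!r}")
        return got

    def by_class(self, cls: str) -> list[PartitionEntry]:
        got = [e for e in self.entries if e.structural_class == cls]
        if not got:
            raise KeyError(f"no partition of class {cls!r}")
        return got

    def select(self, name_or_class: str) -> list[PartitionEntry]:
        """Entries matching a partition name, else a structural class."""
        got = [e for e in self.entries if e.name == name_or_class]
        if not got:
            got = [e for e in self.entries if e.structural_class == name_or_class]
        if not got:
            raise KeyError(f"no partition name or class {name_or_class!r}")
        return got

    def validate_against(self, aln: CodonAlignment) -> None:
        for e in self.entries:
            if e.end_codon > aln.n_codons:
                raise RangeError(
                    f"partition {e.name!r} ends at codon {e.end_codon} but the "
                    f"alignment has {aln.n_codons} codons"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": e.name,
                    "class": e.structural_class,
                    "start_codon": e.start_codon,
                    "end_codon": e.end_codon,
                }
                for e in self.entries
            ]
        )


def read_partition_map(path, aln: CodonAlignment | None = None) -> PartitionMap:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "class": str})
    required = {"name", "class", "start_codon", "end_codon"}
    if not required.issubset(df.columns):
        raise ParseError(f"partition map must have columns {sorted(required)}")
    pmap = PartitionMap(
        [
            PartitionEntry(str(n), str(c), int(s), int(e))
            for n, c, s, e in zip(
                df["name"], df["class"], df["start_codon"], df["end_codon"]
            )
        ]
    )
    if aln is not None:
        pmap.validate_against(aln)
    return pmap


def write_partition_map(pmap: PartitionMap, path) -> None:
    pmap.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# editing-site state tables


@dataclass
class EditingStateTable:
    """Per-species editing-site states.

    ``rows`` is a DataFrame with columns species, site_id, state and
    percent_edited (nullable; the string ``"<10"`` flags sub-threshold
    editing).  GENOMIC_T rows never carry a percent.
    """

    rows: pd.DataFrame

    def __post_init__(self):
        df = self.rows
        required = {"species", "site_id", "state"}
        if not required.issubset(df.columns):
            raise ValueError(f"state table must have columns {sorted(required)}")
        if "percent_edited" not in df.columns:
            df = df.assign(percent_edited=pd.NA)
        bad = set(df["state"]) - EDITING_STATES
        if bad:
            raise ValueError(f"unknown editing states {sorted(bad)}")
        if df.duplicated(["species", "site_id"]).any():
            raise ValueError("duplicate species x site rows")
        has_pct = df["percent_edited"].notna() & (df["percent_edited"].astype(str) != "")
        if (has_pct & (df["state"] == "GENOMIC_T")).any():
            raise ValueError("GENOMIC_T rows must not carry percent_edited")
        self.rows = df.reset_index(drop=True)

    @property
    def site_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["site_id"]))

    def site(self, site_id: str) -> pd.DataFrame:
        sub = self.rows[self.rows["site_id"] == site_id]
        if sub.empty:
            raise KeyError(f"no editing site {site_id!r}")
        return sub

    def states_for(self, site_id: str) -> dict[str, str]:
        sub = self.site(site_id)
        return dict(zip(sub["species"], sub["state"]))


def read_editing_states(path) -> EditingStateTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["percent_edited"] = df.get("percent_edited", "").replace("", pd.NA)
    return EditingStateTable(df)


def write_editing_states(table: EditingStateTable, path) -> None:
    out = table.rows.copy()
    out["percent_edited"] = out["percent_edited"].fillna("")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# chromatogram peak heights


def read_peak_heights(path) -> pd.DataFrame:
    """TSV with columns sample, peak_C, peak_T (one row per measurement)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "peak_C", "peak_T"}
    if not required.issubset(df.columns):
        raise ParseError(f"peak table must have columns {sorted(required)}")
    return df


def write_peak_heights(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AnalysisConfig:
    """Run parameters shared across fits and scans.

    window_codons / step_codons control the sliding-window scan (defaults:
    9-codon windows advanced 3 codons at a time).  Bounds constrain the
    bounded optimiser; frequency_model selects F3x4 (position-specific
    nucleotide frequencies) or uniform codon frequencies.
    """

    window_codons: int = 9
    step_codons: int = 3
    omega_bounds: tuple[float, float] = (1e-4, 50.0)
    kappa_bounds: tuple[float, float] = (0.1, 20.0)
    scaler_bounds: tuple[float, float] = (1e-3, 100.0)
    seed: int = 0
    frequency_model: str = "F3x4"
    n_starts: int = 3
    default_branch_length: float = 0.1

    def __post_init__(self):
        if not (self.window_codons >= self.step_codons >= 1):
            raise ValueError("require window_codons >= step_codons >= 1")
        for lo, hi in (self.omega_bounds, self.kappa_bounds, self.scaler_bounds):
            if not (0 < lo < hi):
                raise ValueError(f"bounds must be positive with lo < hi, got ({lo}, {hi})")
        if self.frequency_model not in {"F3x4", "uniform"}:
            raise ValueError("frequency_model must be 'F3x4' or 'uniform'")


def read_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("omega_bounds", "kappa_bounds", "scaler_bounds"):
        if key in data:
            data[key] = tuple(data[key])
    return AnalysisConfig(**data)


def write_config(cfg: AnalysisConfig, path) -> None:
    data = {
        "window_codons": cfg.window_codons,
        "step_codons": cfg.step_codons,
        "omega_bounds": list(cfg.omega_bounds),
        "kappa_bounds": list(cfg.kappa_bounds),
        "scaler_bounds": list(cfg.scaler_bounds),
        "seed": cfg.seed,
        "frequency_model": cfg.frequency_model,
        "n_starts": cfg.n_starts,
        "default_branch_length": cfg.default_branch_length,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
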