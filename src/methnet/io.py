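"""Readers and writers for the on-disk formats.

Matrices are TSV with variable ids in the first column and sample ids in
the header row (variables x samples on disk, transposed to samples x
variables in memory).  Genomic inputs are BED (0-based half-open,
converted to 1-based inclusive internally), GFF3 (genes; already
1-based) and BEDPE (interaction anchor pairs).  Probe positions are the
interval midpoint; gene TSS is the interval start on '+' and the end on
'-'.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from .containers import GenomicAnnotation, Kind, OmicsMatrix
from .dre import AnchorPair
from .enrichment import MotifHit
from .circuits import SeRegion
from .errors import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- matrices
def read_matrix(path, kind: Kind) -> OmicsMatrix:
    """Read a variables x samples TSV into an OmicsMatrix."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()].tolist()
        raise ValidationError(f"{path}: duplicated variable ids: {dup}")
    for col in frame.columns:
        bad = pd.to_numeric(frame[col], errors="coerce")
        if bad.isna().sum() > frame[col].isna().sum():
            row = frame.index[bad.isna() & frame[col].notna()][0]
            raise ValidationError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
    data = frame.T.astype(float)
    if kind == "methylation":
        vals = data.to_numpy()
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError(
                f"{path}: methylation beta values outside [0, 1]"
            )
    return OmicsMatrix.from_frame(data, kind)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write back in the on-disk orientation (variables x samples)."""
    matrix.data.T.to_csv(path, sep="\t", index_label="id")


# ----------------------------------------------------------------- regions
def _bed_rows(path, min_cols: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ValidationError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def _bed_interval(path, lineno, start_s, end_s) -> tuple[int, int]:
    start, end = int(start_s), int(end_s)
    if start >= end:
        raise ValidationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
    return start + 1, end  # 0-based half-open -> 1-based inclusive


def read_probe_bed(path) -> dict[str, GenomicAnnotation]:
    """Probe coordinates: BED4; position = interval midpoint (1-based)."""
    out = {}
    for lineno, f in _bed_rows(path, 4):
        start1, end1 = _bed_interval(path, lineno, f[1], f[2])
        pos = (start1 + end1) // 2
        out[f[3]] = GenomicAnnotation(f[3], f[0], pos, "probe")
    return out


def read_gene_bed(path) -> dict[str, GenomicAnnotation]:
    """Gene intervals: BED6; TSS from strand (start on +, end on -)."""
    out = {}
    for lineno, f in _bed_rows(path, 6):
        start1, end1 = _bed_interval(path, lineno, f[1], f[2])
        strand = f[5]
        if strand not in {"+", "-"}:
            raise ValidationError(f"{path}:{lineno}: unknown strand {strand!r}")
        tss = start1 if strand == "+" else end1
        out[f[3]] = GenomicAnnotation(f[3], f[0], tss, "gene", strand)
    return out


def read_gff3_genes(path) -> dict[str, GenomicAnnotation]:
    """Gene records from GFF3 (1-based inclusive already); name from ID=/Name=."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValidationError(f"{path}:{lineno}: GFF3 needs 9 columns")
            if f[2] != "gene":
                continue
            chrom, start, end, strand = f[0], int(f[3]), int(f[4]), f[6]
            if strand not in {"+", "-"}:
                raise ValidationError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID")
            if not name:
                raise ValidationError(f"{path}:{lineno}: gene without ID/Name")
            tss = start if strand == "+" else end
            out[name] = GenomicAnnotation(name, chrom, tss, "gene", strand)
    return out


def read_bedpe(path) -> list[AnchorPair]:
    """Interaction anchor pairs: BEDPE6, converted to 1-based inclusive."""
    out = []
    for lineno, f in _bed_rows(path, 6):
        s1, e1 = _bed_interval(path, lineno, f[1], f[2])
        s2, e2 = _bed_interval(path, lineno, f[4], f[5])
        out.append(AnchorPair(f[0], s1, e1, f[3], s2, e2))
    return out


def read_motif_bed(path) -> list[MotifHit]:
    """TF motif hits: BED4 with the TF name in column 4."""
    out = []
    for lineno, f in _bed_rows(path, 4):
        s, e = _bed_interval(path, lineno, f[1], f[2])
        out.append(MotifHit(tf=f[3], chrom=f[0], start=s, end=e))
    return out


def read_se_bed(path) -> list[SeRegion]:
    """Super-enhancer regions: BED3+ (name optional in column 4)."""
    out = []
    for lineno, f in _bed_rows(path, 3):
        s, e = _bed_interval(path, lineno, f[1], f[2])
        name = f[3] if len(f) > 3 else f"SE{lineno}"
        out.append(SeRegion(name, f[0], s, e))
    return out


def write_annotations_bed(annotations, path, kind: str) -> None:
    """Write probe (BED4) or gene (BED6) annotations; inverse of the readers."""
    with open(path, "w") as fh:
        for ann in sorted(annotations.values(), key=lambda a: (a.chrom, a.position)):
            if ann.kind != kind:
                continue
            if kind == "probe":
                fh.write(f"{ann.chrom}\t{ann.position - 1}\t{ann.position}\t{ann.id}\n")
            else:
                fh.write(
                    f"{ann.chrom}\t{ann.position - 1}\t{ann.position}\t"
                    f"{ann.id}\t.\t{ann.strand}\n"
                )


# ------------------------------------------------------------------ config
@dataclasses.dataclass
class RunConfig:
    """Resolved run configuration, serialized next to every run's outputs."""

    expression: str = ""
    methylation: str = ""
    probes: str = ""
    genes: str = ""
    interactions: str = ""
    motifs: str = ""
    super_enhancers: str = ""
    output_dir: str = "."
    window_bp: int = 300_000
    flank_bp: int = 250
    p_cutoff: float = 0.01
    mi_floor_bits: float = 0.1
    or_threshold: float = 1.05
    dynamics_tol: float = 0.05
    n_perm: int = 100
    n_random_networks: int = 200
    seed: int = 0

    def validate_paths(self) -> None:
        for name in ("expression", "methylation", "probes", "genes",
                     "interactions", "motifs", "super_enhancers"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ValidationError(f"config: {name} path does not exist: {value}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
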