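"""Readers and writers for every external representation the pipeline touches.

Coordinate conventions
----------------------
Internal coordinates are **1-based inclusive**: an interval spanning positions
``start..end`` has length ``end - start + 1``.  BED files on disk are 0-based
half-open, so reading converts ``start_internal = bed_start + 1``,
``end_internal = bed_end`` and writing is the exact inverse.  Chromosome
labels are normalized to the ``chrN`` form on input and compared exactly
afterwards.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssocRecord",
    "StudyMeta",
    "GenomicInterval",
    "LoopPair",
    "LDMatrix",
    "FormatError",
    "ValidationError",
    "normalize_chrom",
    "chrom_sort_key",
    "read_summary_stats",
    "write_summary_stats",
    "read_study_table",
    "write_study_table",
    "read_intervals",
    "write_intervals",
    "read_loops",
    "write_loops",
    "write_ucsc_track",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_category_map",
    "write_category_map",
    "read_gene_models",
    "write_gene_models",
    "read_consequence_table",
    "write_consequence_table",
    "read_reference_panel",
    "write_reference_panel",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Rows violate hard record invariants; message lists the offenders."""


_CHROM_RE = re.compile(r"^(chr)?([0-9XYM]+T?)$", re.IGNORECASE)


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label to ``chrN`` form (``1`` -> ``chr1``)."""
    label = str(label).strip()
    m = _CHROM_RE.match(label)
    if not m:
        raise FormatError(f"unrecognized chromosome label: {label!r}")
    return "chr" + m.group(2).upper().replace("MT", "M")


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    body = chrom[3:] if chrom.startswith("chr") else chrom
    if body.isdigit():
        return (int(body), "")
    return (1000, body)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AssocRecord:
    """One variant's association statistics for one study.

    ``eaf_source`` tracks frequency provenance: ``observed`` (came with the
    data), ``imputed`` (filled from a reference panel) or ``missing``.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None
    n: int
    study_id: str = ""
    eaf_source: str = "observed"

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.pos < 1:
            problems.append(f"pos {self.pos} < 1")
        if self.se is not None and not math.isnan(self.se) and self.se <= 0:
            problems.append(f"se {self.se} <= 0")
        if not (0 < self.pvalue <= 1):
            problems.append(f"pvalue {self.pvalue} outside (0, 1]")
        if self.eaf is not None and not math.isnan(self.eaf) and not (0 <= self.eaf <= 1):
            problems.append(f"eaf {self.eaf} outside [0, 1]")
        return problems

    def has_missing_stats(self) -> bool:
        for v in (self.beta, self.se, self.pvalue):
            if v is None or math.isnan(v):
                return True
        return False


@dataclass
class StudyMeta:
    """Study-level metadata: a GWAS carries a trait, an eQTL a gene+tissue."""

    study_id: str
    kind: str  # "gwas" | "eqtl"
    trait_id: str = ""
    gene_id: str = ""
    tissue_id: str = ""
    n: int = 0
    n_cases: int | None = None
    n_controls: int | None = None
    trait_type: str = "quantitative"  # "quantitative" | "case_control"

    def __post_init__(self) -> None:
        if self.kind not in ("gwas", "eqtl"):
            raise ValidationError(f"study kind must be gwas|eqtl, got {self.kind!r}")
        if self.kind == "gwas" and not self.trait_id:
            raise ValidationError(f"gwas study {self.study_id} lacks trait_id")
        if self.kind == "eqtl" and not (self.gene_id and self.tissue_id):
            raise ValidationError(f"eqtl study {self.study_id} lacks gene_id/tissue_id")


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval; length = end - start + 1."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class LoopPair:
    """A chromatin loop: two same-chromosome anchors, a ordered before b."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValidationError("loop anchors on different chromosomes")
        if self.anchor_a.start > self.anchor_b.start:
            raise ValidationError("loop anchors not ordered by start")

    @property
    def chrom(self) -> str:
        return self.anchor_a.chrom

    @property
    def span(self) -> GenomicInterval:
        """Outer span from the left edge of anchor a to the right edge of b."""
        return GenomicInterval(self.chrom, self.anchor_a.start, self.anchor_b.end)

    @property
    def inner_span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.anchor_a.end, self.anchor_b.start)


@dataclass
class LDMatrix:
    """Pairwise correlation matrix r over an ordered variant list."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        q = len(self.variant_ids)
        if self.r.shape != (q, q):
            raise ValidationError(f"LD matrix shape {self.r.shape} != ({q}, {q})")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != q:
            raise ValidationError("duplicate variant ids in LD matrix")

    def validate(self, tol: float = 1e-6) -> None:
        if not np.allclose(self.r, self.r.T, atol=tol):
            raise ValidationError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=tol):
            raise ValidationError("LD matrix diagonal not 1")
        if np.any(np.abs(self.r) > 1 + tol):
            raise ValidationError("LD entries outside [-1, 1]")
        w = np.linalg.eigvalsh((self.r + self.r.T) / 2)
        if w.min() < -1e-6:
            raise ValidationError(f"LD matrix not PSD (min eigenvalue {w.min():.3g})")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2(self, a: str, b: str) -> float:
        try:
            return float(self.r[self._index[a], self._index[b]] ** 2)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} absent from LD matrix") from None

    def submatrix(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


class BlockLD:
    """LD over disjoint blocks: r = 0 between blocks, the block matrix within."""

    def __init__(self, blocks: Iterable[LDMatrix]):
        self.blocks = list(blocks)
        self._which: dict[str, int] = {}
        for i, b in enumerate(self.blocks):
            for v in b.variant_ids:
                if v in self._which:
                    raise ValidationError(f"variant {v} in more than one LD block")
                self._which[v] = i

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._which

    def r2(self, a: str, b: str) -> float:
        for v in (a, b):
            if v not in self._which:
                raise KeyError(f"variant {v!r} absent from LD matrix")
        ia, ib = self._which[a], self._which[b]
        if ia != ib:
            return 0.0
        return self.blocks[ia].r2(a, b)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "beta",
    "se",
    "pvalue",
    "eaf",
    "n",
)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise FormatError(
        f"{path}: cannot detect delimiter (only tab and comma are auto-detected)"
    )


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    study_id: str | None = None,
    delimiter: str | None = None,
) -> list[AssocRecord]:
    """Read a delimited summary-statistics table into validated records.

    ``column_map`` maps the canonical column names (``variant_id``, ``chrom``,
    ``pos``, ``ref``, ``alt``, ``beta``, ``se``, ``pvalue``, ``eaf``, ``n``)
    to the names used in the source file.  Rows violating hard invariants
    raise :class:`ValidationError` naming each offending line; missing ``eaf``
    is retained (it may be filled from a reference panel later).
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    colmap = {c: c for c in SUMMARY_COLUMNS}
    if column_map:
        colmap.update(column_map)
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    if study_id is None:
        study_id = df["study_id"].iloc[0] if "study_id" in df.columns and len(df) else ""

    records: list[AssocRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        rowd = dict(zip(df.columns, row))
        try:
            eaf_raw = rowd[colmap["eaf"]]
            eaf = None if eaf_raw in (None, "", "NA", "nan") or pd.isna(eaf_raw) else float(eaf_raw)
            rec = AssocRecord(
                variant_id=str(rowd[colmap["variant_id"]]),
                chrom=normalize_chrom(rowd[colmap["chrom"]]),
                pos=int(rowd[colmap["pos"]]),
                ref=str(rowd[colmap["ref"]]),
                alt=str(rowd[colmap["alt"]]),
                beta=float(rowd[colmap["beta"]]),
                se=float(rowd[colmap["se"]]),
                pvalue=float(rowd[colmap["pvalue"]]),
                eaf=eaf,
                n=int(float(rowd[colmap["n"]])),
                study_id=study_id,
                eaf_source="missing" if eaf is None else "observed",
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"line {i}: {exc}")
            continue
        problems = rec.validate()
        if problems:
            errors.append(f"line {i}: " + "; ".join(problems))
        else:
            records.append(rec)
    if errors:
        raise ValidationError(f"{path}: invalid rows:\n" + "\n".join(errors))
    return records


def write_summary_stats(records: Iterable[AssocRecord], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pvalue": repr(r.pvalue),
                "eaf": "" if r.eaf is None else repr(r.eaf),
                "n": r.n,
                "study_id": r.study_id,
            }
        )
    pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS) + ["study_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_study_table(path: str | Path) -> dict[str, StudyMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    metas = {}
    for _, row in df.iterrows():
        metas[row["study_id"]] = StudyMeta(
            study_id=row["study_id"],
            kind=row["kind"],
            trait_id=row.get("trait_id", ""),
            gene_id=row.get("gene_id", ""),
            tissue_id=row.get("tissue_id", ""),
            n=int(float(row["n"])) if row.get("n") else 0,
            trait_type=row.get("trait_type") or "quantitative",
        )
    return metas


def write_study_table(metas: Iterable[StudyMeta], path: str | Path) -> None:
    rows = [
        {
            "study_id": m.study_id,
            "kind": m.kind,
            "trait_id": m.trait_id,
            "gene_id": m.gene_id,
            "tissue_id": m.tissue_id,
            "n": m.n,
            "trait_type": m.trait_type,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals (BED) and loops (BEDPE)
# ---------------------------------------------------------------------------


def interval_from_bed(chrom: str, bed_start: int, bed_end: int, name: str = "",
                      score: float | None = None) -> GenomicInterval:
    if bed_end <= bed_start:
        raise FormatError(f"BED end {bed_end} <= start {bed_start}")
    return GenomicInterval(normalize_chrom(chrom), bed_start + 1, bed_end, name, score)


def interval_to_bed(iv: GenomicInterval) -> tuple[str, int, int]:
    return iv.chrom, iv.start - 1, iv.end


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
    if format != "bed":
        raise FormatError(f"unsupported interval format: {format}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                iv = interval_from_bed(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3] if len(fields) > 3 else "",
                    float(fields[4]) if len(fields) > 4 and fields[4] != "." else None,
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, s, e = interval_to_bed(iv)
            fields = [chrom, str(s), str(e)]
            if iv.name or iv.score is not None:
                fields.append(iv.name or ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


def read_loops(path: str | Path) -> tuple[list[LoopPair], int]:
    """Read BEDPE loops; returns (loops, inter-chromosomal skip count)."""
    loops = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: fewer than 6 BEDPE fields")
            try:
                a = interval_from_bed(fields[0], int(fields[1]), int(fields[2]))
                b = interval_from_bed(fields[3], int(fields[4]), int(fields[5]))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if a.chrom != b.chrom:
                skipped += 1
                continue
            if a.start > b.start:
                a, b = b, a
            loops.append(LoopPair(a, b))
    return loops, skipped


def write_loops(loops: Iterable[LoopPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            ca, sa, ea = interval_to_bed(lp.anchor_a)
            cb, sb, eb = interval_to_bed(lp.anchor_b)
            fh.write(f"{ca}\t{sa}\t{ea}\t{cb}\t{sb}\t{eb}\n")


def write_ucsc_track(
    items: Iterable, path: str | Path, track_name: str = "pleioqtl"
) -> None:
    """Write a UCSC custom track (BED, 0-based half-open, sorted).

    Items must expose ``chrom``, ``start``, ``end`` (1-based inclusive) and
    optionally ``name``.
    """
    rows = []
    for it in items:
        name = getattr(it, "name", "") or getattr(it, "variant_id", "") or "."
        rows.append((it.chrom, it.start - 1, it.end, name))
    rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1]))
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}" description="{track_name}"\n')
        for chrom, s, e, name in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


# ---------------------------------------------------------------------------
# LD matrices, category maps, gene models, consequence tables, panels
# ---------------------------------------------------------------------------


def read_ld_matrix(path: str | Path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise FormatError(f"{path}: LD matrix row and column ids differ")
    return LDMatrix(ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


def read_category_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV trait_id -> category; every trait maps to one category."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if len(header) < 2:
            raise FormatError(f"{path}: expected two tab-separated columns")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            trait, category = row[0], row[1]
            if trait in mapping and mapping[trait] != category:
                raise FormatError(
                    f"{path}:{lineno}: trait {trait!r} mapped to two categories"
                )
            mapping[trait] = category
    return mapping


def write_category_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("trait_id\tcategory\n")
        for trait in sorted(mapping):
            fh.write(f"{trait}\t{mapping[trait]}\n")


def read_gene_models(path: str | Path) -> dict[str, GenomicInterval]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return {
        str(row.gene_id): GenomicInterval(
            normalize_chrom(row.chrom), int(row.start), int(row.end), str(row.gene_id)
        )
        for row in df.itertuples(index=False)
    }


def write_gene_models(models: Mapping[str, GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\n")
        for gid in sorted(models):
            iv = models[gid]
            fh.write(f"{gid}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_consequence_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["variant_id"], df["consequence"]))


def write_consequence_table(table: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tconsequence\n")
        for vid in sorted(table):
            fh.write(f"{vid}\t{table[vid]}\n")


def read_reference_panel(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    return dict(zip(df["variant_id"], df["eaf"].astype(float)))


def write_reference_panel(panel: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\teaf\n")
        for vid in sorted(panel):
            fh.write(f"{vid}\t{panel[vid]!r}\n")
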