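"""Exon-21 skipping vs inclusion quantification from splice-junction evidence.

NKCC1 (*Slc12a2*) is expressed as two splice variants: NKCC1a includes the
48-nt cassette exon-21 (16 codons in the intracellular C-terminus) and NKCC1b
skips it.  Given spliced alignments (SAM/BAM) or a junction count table, this
module extracts intron gaps, classifies each junction against an exon model
(skip = donor of exon-20 joined to acceptor of exon-22; inclusion = either
flanking junction of exon-21), and reports the per-sample NKCC1a/NKCC1b
fractions as integer percentages.

All intron intervals are 0-based half-open (BED convention); STAR
``SJ.out.tab`` tables (1-based closed) are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

__all__ = [
    "ExonModel",
    "VariantFractions",
    "extract_junctions",
    "read_junction_tsv",
    "read_star_sj_tab",
    "classify_junctions",
    "compute_variant_fractions",
    "variant_fractions_by_sample",
]

JX_CLASSES = ("skip", "include_5p", "include_3p", "other")

#: reference-consuming CIGAR operations (M, D, N, =, X)
_REF_OPS = {0, 2, 3, 7, 8}


@dataclass(frozen=True)
class ExonModel:
    """Ordered exon intervals of one transcript with a focal cassette exon.

    ``exons`` are 0-based half-open genomic intervals, strictly ordered and
    non-overlapping; ``focal_index`` selects the cassette exon (0-based index
    into ``exons``), which must have a neighbour on both sides.
    """

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    focal_index: int

    def __post_init__(self) -> None:
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty exon interval ({start}, {end})")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError("exons must be ordered and non-overlapping")
        if not 0 < self.focal_index < len(self.exons) - 1:
            raise ValueError("focal exon needs a flanking exon on both sides")

    @property
    def focal_length(self) -> int:
        s, e = self.exons[self.focal_index]
        return e - s

    @property
    def skip_template(self) -> tuple[int, int]:
        return (
            self.exons[self.focal_index - 1][1],
            self.exons[self.focal_index + 1][0],
        )

    @property
    def include_5p_template(self) -> tuple[int, int]:
        return (
            self.exons[self.focal_index - 1][1],
            self.exons[self.focal_index][0],
        )

    @property
    def include_3p_template(self) -> tuple[int, int]:
        return (
            self.exons[self.focal_index][1],
            self.exons[self.focal_index + 1][0],
        )

    @classmethod
    def from_bed(cls, path: str | Path, focal_index: int) -> "ExonModel":
        """Read one exon per 6-column BED line (all lines one transcript)."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        df = df.sort_values("start")
        return cls(
            chrom=str(df["chrom"].iloc[0]),
            strand=str(df["strand"].iloc[0]),
            exons=tuple(zip(df["start"].astype(int), df["end"].astype(int))),
            focal_index=focal_index,
        )

    @classmethod
    def from_gtf(
        cls, path: str | Path, transcript_id: str, focal_index: int
    ) -> "ExonModel":
        """Collect the exon features of one transcript from a GTF file."""
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        exons = [
            f
            for f in db.features_of_type("exon")
            if transcript_id in f.attributes.get("transcript_id", [])
        ]
        if not exons:
            raise ValueError(f"no exons for transcript {transcript_id!r}")
        exons.sort(key=lambda f: f.start)
        return cls(
            chrom=exons[0].seqid,
            strand=exons[0].strand,
            exons=tuple((f.start - 1, f.end) for f in exons),  # GTF is 1-based closed
            focal_index=focal_index,
        )


@dataclass(frozen=True)
class VariantFractions:
    """NKCC1a (exon-21 including) vs NKCC1b (skipping) evidence for one sample."""

    n_skip: int
    n_include: int

    @property
    def total(self) -> int:
        return self.n_skip + self.n_include

    @property
    def frac_a(self) -> float:
        return self.n_include / self.total

    @property
    def frac_b(self) -> float:
        return 1.0 - self.frac_a

    @property
    def percent_a(self) -> int:
        return int(round(100.0 * self.frac_a))

    @property
    def percent_b(self) -> int:
        # reconcile rounding so the pair always sums to 100
        return 100 - self.percent_a


def _junctions_from_alignment(read: pysam.AlignedSegment) -> Iterable[tuple[int, int]]:
    """Walk the CIGAR from the alignment start; every N op is one junction."""
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op == 3:  # N: intron gap
            yield (pos, pos + length)
        if op in _REF_OPS:
            pos += length


def extract_junctions(
    source: str | Path | pd.DataFrame,
    region: tuple[str, int, int] | None = None,
) -> pd.DataFrame:
    """Aggregate splice-junction read counts from alignments or a table.

    ``source`` may be a SAM/BAM path (every N gap in a read's CIGAR counts
    once toward its junction) or a junction TSV path / DataFrame with columns
    ``chrom, intron_start, intron_end, n_reads``.  ``region`` optionally
    restricts to junctions contained in ``(chrom, start, end)``.  Returns one
    row per unique intron interval with its aggregated read count.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if path.suffix.lower() in {".sam", ".bam", ".cram"}:
            rows: dict[tuple[str, int, int], int] = {}
            with pysam.AlignmentFile(str(path), check_sq=False) as fh:
                for read in fh.fetch(until_eof=True):
                    if read.is_unmapped or read.cigartuples is None:
                        continue
                    chrom = read.reference_name
                    for start, end in _junctions_from_alignment(read):
                        key = (chrom, start, end)
                        rows[key] = rows.get(key, 0) + 1
            df = pd.DataFrame(
                [
                    {"chrom": c, "intron_start": s, "intron_end": e, "n_reads": n}
                    for (c, s, e), n in rows.items()
                ],
                columns=["chrom", "intron_start", "intron_end", "n_reads"],
            )
        else:
            df = read_junction_tsv(path)
    if (df["n_reads"] < 0).any():
        raise ValueError("negative read counts")
    df = (
        df.groupby(["chrom", "intron_start", "intron_end"], as_index=False)["n_reads"]
        .sum()
        .sort_values(["chrom", "intron_start", "intron_end"])
        .reset_index(drop=True)
    )
    if region is not None:
        chrom, start, end = region
        df = df[
            (df["chrom"] == chrom)
            & (df["intron_start"] >= start)
            & (df["intron_end"] <= end)
        ].reset_index(drop=True)
    return df


def read_junction_tsv(path: str | Path) -> pd.DataFrame:
    """Read the package's native junction table (0-based half-open introns)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "intron_start", "intron_end", "n_reads"}
    if not required.issubset(df.columns):
        raise ValueError(f"junction TSV must have columns {sorted(required)}")
    return df[["chrom", "intron_start", "intron_end", "n_reads"]]


def read_star_sj_tab(path: str | Path) -> pd.DataFrame:
    """Read a STAR ``SJ.out.tab`` and convert to 0-based half-open introns.

    STAR reports the intron as 1-based closed [first base, last base]; the
    half-open interval is [first-1, last).  Unique-mapping read counts
    (column 7) are used.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=[
            "chrom", "first_base", "last_base", "strand",
            "motif", "annotated", "n_unique", "n_multi", "overhang",
        ],
    )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "intron_start": df["first_base"].astype(int) - 1,
            "intron_end": df["last_base"].astype(int),
            "n_reads": df["n_unique"].astype(int),
        }
    )


def classify_junctions(
    junctions: pd.DataFrame, model: ExonModel, tolerance: int = 0
) -> pd.DataFrame:
    """Label each junction skip / include_5p / include_3p / other.

    Matching is exact against the model's three junction templates by default;
    ``tolerance`` allows +/- that many bases on both coordinates for noisy
    aligners.
    """
    templates = {
        "skip": model.skip_template,
        "include_5p": model.include_5p_template,
        "include_3p": model.include_3p_template,
    }
    out = junctions.copy()

    def classify(row) -> str:
        if row["chrom"] != model.chrom:
            return "other"
        for name, (ts, te) in templates.items():
            if (
                abs(int(row["intron_start"]) - ts) <= tolerance
                and abs(int(row["intron_end"]) - te) <= tolerance
            ):
                return name
        return "other"

    out["jx_class"] = (
        out.apply(classify, axis=1) if len(out) else pd.Series(dtype=object)
    )
    return out


def compute_variant_fractions(
    junctions: pd.DataFrame, inclusion_rule: str = "five_prime"
) -> VariantFractions | None:
    """Aggregate classified junctions into NKCC1a/NKCC1b evidence.

    ``inclusion_rule`` controls how the two exon-21 flanking junctions are
    tallied: ``five_prime`` counts only the exon-20 -> exon-21 junction (one
    transcript contributes one inclusion read), ``mean`` the rounded mean of
    both flanks, ``sum`` both flanks.  Returns None (with a warning) for a
    sample with no skip or inclusion evidence.
    """
    totals = junctions.groupby("jx_class")["n_reads"].sum()
    n_skip = int(totals.get("skip", 0))
    n5 = int(totals.get("include_5p", 0))
    n3 = int(totals.get("include_3p", 0))
    if inclusion_rule == "five_prime":
        n_include = n5
    elif inclusion_rule == "mean":
        n_include = int(round((n5 + n3) / 2.0))
    elif inclusion_rule == "sum":
        n_include = n5 + n3
    else:
        raise ValueError(f"unknown inclusion_rule {inclusion_rule!r}")
    if n_skip + n_include == 0:
        warnings.warn("no skip or inclusion evidence; fractions undefined", stacklevel=2)
        return None
    return VariantFractions(n_skip=n_skip, n_include=n_include)


def variant_fractions_by_sample(
    samples: Mapping[str, pd.DataFrame],
    inclusion_rule: str = "five_prime",
    pool: bool = True,
) -> pd.DataFrame:
    """Per-sample (and optionally pooled) variant fraction table."""
    rows = []
    pooled_frames = []
    for sample_id, df in samples.items():
        vf = compute_variant_fractions(df, inclusion_rule)
        pooled_frames.append(df)
        if vf is None:
            continue
        rows.append(
            {
                "sample_id": sample_id,
                "n_skip": vf.n_skip,
                "n_include": vf.n_include,
                "percent_a": vf.percent_a,
                "percent_b": vf.percent_b,
            }
        )
    if pool and pooled_frames:
        vf = compute_variant_fractions(pd.concat(pooled_frames), inclusion_rule)
        if vf is not None:
            rows.append(
                {
                    "sample_id": "pooled",
                    "n_skip": vf.n_skip,
                    "n_include": vf.n_include,
                    "percent_a": vf.percent_a,
                    "percent_b": vf.percent_b,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "n_skip", "n_include", "percent_a", "percent_b"]
    )
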