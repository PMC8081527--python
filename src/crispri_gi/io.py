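"""Tabular I/O for pooled-screen count data.

All files are plain TSV with a header row, UTF-8, '.' decimal separator and
no quoting — the dialect screen-count exports commonly use.  Three input
tables feed the pipeline:

* guide annotation: ``guide_id  target_gene  is_control`` (is_control 0/1);
* sample metadata:  ``sample_id  background  timepoint  replicate``;
* raw counts:       ``guide_id`` plus one integer column per sample_id.

Missing cells are an error rather than an implicit zero, so that a genuine
dropout (count 0) stays distinguishable from a truncated file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

REFERENCE = "reference"
MUTANT = "mutant"
BACKGROUNDS = (REFERENCE, MUTANT)

START = "start"
END = "end"
TIMEPOINTS = (START, END)

RAW = "raw"
NORMALIZED = "normalized"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequencing sample of the pooled library."""

    sample_id: str
    background: str  # reference | mutant
    timepoint: str  # start | end
    replicate: int

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise FormatError(
                f"sample {self.sample_id!r}: background must be one of "
                f"{BACKGROUNDS}, got {self.background!r}"
            )
        if self.timepoint not in TIMEPOINTS:
            raise FormatError(
                f"sample {self.sample_id!r}: timepoint must be one of "
                f"{TIMEPOINTS}, got {self.timepoint!r}"
            )
        if int(self.replicate) < 1:
            raise FormatError(
                f"sample {self.sample_id!r}: replicate must be a positive "
                f"integer, got {self.replicate!r}"
            )


@dataclass
class GuideAnnotation:
    """Guide → gene map of the library, including non-targeting controls.

    ``frame`` has columns ``guide_id``, ``target_gene`` (None for controls)
    and ``is_control`` (bool), in file order.  Exactly one of target_gene /
    is_control holds per guide, and guide_ids are unique.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        dup = f["guide_id"][f["guide_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate guide_id {dup.iloc[0]!r}")
        has_gene = f["target_gene"].notna() & (f["target_gene"] != "")
        bad = has_gene == f["is_control"]
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"line {i + 2}: guide {f['guide_id'].iloc[i]!r} must have "
                "exactly one of target_gene or is_control"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def guide_ids(self) -> list[str]:
        return self.frame["guide_id"].tolist()

    @property
    def control_ids(self) -> list[str]:
        return self.frame.loc[self.frame["is_control"], "guide_id"].tolist()

    @property
    def genes(self) -> list[str]:
        """Targeted genes, in first-appearance order."""
        g = self.frame.loc[~self.frame["is_control"], "target_gene"]
        return list(dict.fromkeys(g))

    def gene_to_guides(self) -> dict[str, list[str]]:
        t = self.frame.loc[~self.frame["is_control"]]
        out: dict[str, list[str]] = {}
        for gid, gene in zip(t["guide_id"], t["target_gene"]):
            out.setdefault(gene, []).append(gid)
        return out


@dataclass
class CountTable:
    """Guides × samples read-count matrix.

    ``counts`` is indexed by guide_id with one column per sample_id, in the
    order of ``samples``.  ``stage`` is ``raw`` (integer counts) or
    ``normalized`` (columns scaled to a common total).
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]
    stage: str = RAW

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise FormatError(
                "count columns do not match sample metadata order: "
                f"{list(self.counts.columns)} vs {ids}"
            )
        triples = {(s.background, s.timepoint, s.replicate) for s in self.samples}
        if len(triples) != len(self.samples):
            raise FormatError("(background, timepoint, replicate) triples not unique")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise FormatError("negative count values")
        if self.stage == RAW and not np.allclose(vals, np.round(vals)):
            raise FormatError("raw-stage counts must be integers")
        if self.stage == NORMALIZED and len(ids) > 1:
            sums = vals.sum(axis=0)
            if not np.allclose(sums, sums.mean(), rtol=1e-9):
                raise FormatError("normalized column sums differ beyond tolerance")

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    def sample(self, background: str, timepoint: str) -> list[SampleMeta]:
        return [
            s
            for s in self.samples
            if s.background == background and s.timepoint == timepoint
        ]


@dataclass
class GeneInteraction:
    """Per-gene genetic-interaction call.

    ``gi_score`` is the signed median Δlog2FC (mutant − reference) over the
    gene's surviving guides; ``mhg_stat``/``pvalue``/``qvalue`` come from the
    two-directional exact minimum-hypergeometric test.  Genes with no guides
    surviving the filters carry NaN statistics and ``tested=False``.
    """

    gene: str
    n_guides: int
    gi_score: float = math.nan
    mhg_stat: float = math.nan
    pvalue: float = math.nan
    qvalue: float = math.nan
    direction: str | None = None  # negative | positive
    tier: str = "none"  # none | tier1 | tier2
    tested: bool = True


# ---------------------------------------------------------------------------
# readers


def read_guide_annotation(path) -> GuideAnnotation:
    """Parse a guide-annotation TSV, validating the guide→gene map."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["guide_id", "target_gene", "is_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"guide annotation missing columns {missing}")
    bad_flag = ~df["is_control"].isin(["0", "1"])
    if bad_flag.any():
        i = int(np.flatnonzero(bad_flag)[0])
        raise FormatError(
            f"line {i + 2}: is_control must be 0 or 1, got "
            f"{df['is_control'].iloc[i]!r}"
        )
    frame = pd.DataFrame(
        {
            "guide_id": df["guide_id"],
            "target_gene": df["target_gene"].replace("", None),
            "is_control": df["is_control"] == "1",
        }
    )
    return GuideAnnotation(frame)


def read_sample_meta(path) -> list[SampleMeta]:
    """Parse the sample-metadata TSV into a list of :class:`SampleMeta`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "background", "timepoint", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"sample metadata missing columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample_id {dup.iloc[0]!r}")
    samples = []
    for i, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except ValueError:
            raise FormatError(
                f"line {i + 2}: replicate must be an integer, got "
                f"{row['replicate']!r}"
            ) from None
        samples.append(
            SampleMeta(row["sample_id"], row["background"], row["timepoint"], rep)
        )
    _check_paired(samples)
    return samples


def _check_paired(samples: list[SampleMeta]) -> None:
    for bg in {s.background for s in samples}:
        tps = {s.timepoint for s in samples if s.background == bg}
        if tps != set(TIMEPOINTS):
            raise FormatError(
                f"background {bg!r} needs at least one start and one end sample"
            )


def read_count_table(
    path, meta: list[SampleMeta], annotation: GuideAnnotation | None = None
) -> tuple[CountTable, list[str]]:
    """Parse a raw count TSV against sample metadata.

    Returns the raw-stage table plus a warning list naming guides that are
    absent from ``annotation`` (they are retained, never dropped: such guides
    simply belong to no gene and are not controls).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "guide_id":
        raise FormatError("first column of a count table must be guide_id")
    by_id = {s.sample_id: s for s in meta}
    unknown = [c for c in df.columns[1:] if c not in by_id]
    if unknown:
        raise FormatError(
            f"count column {unknown[0]!r} absent from sample metadata"
        )
    dup = df["guide_id"][df["guide_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate guide_id {dup.iloc[0]!r} in count table")
    counts = pd.DataFrame(index=pd.Index(df["guide_id"], name="guide_id"))
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"count for guide {df['guide_id'].iloc[i]!r}, sample {col!r} "
                f"is not a nonnegative integer: {df[col].iloc[i]!r}"
            )
        counts[col] = vals.to_numpy(dtype=np.int64)
    samples = [by_id[c] for c in df.columns[1:]]
    warnings: list[str] = []
    if annotation is not None:
        known = set(annotation.guide_ids)
        warnings = [
            f"guide {g!r} present in counts but absent from annotation"
            for g in counts.index
            if g not in known
        ]
    return CountTable(counts, samples, stage=RAW), warnings


# ---------------------------------------------------------------------------
# writers

_RESULT_COLUMNS = [
    "gene",
    "n_guides",
    "gi_score",
    "mhg_stat",
    "pvalue",
    "qvalue",
    "direction",
    "tier",
]


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return format(float(x), ".12g")


def write_gene_results(results: list[GeneInteraction], path) -> None:
    """Write gene-level interaction calls as TSV.

    Rows are sorted by qvalue ascending (untested genes last) then by
    |gi_score| descending; numeric fields carry 12 significant digits so a
    read-back round-trips losslessly at that precision.
    """
    if not results:
        raise DataError("no gene results to write")

    def key(r: GeneInteraction):
        q = r.qvalue if not math.isnan(r.qvalue) else math.inf
        g = abs(r.gi_score) if not math.isnan(r.gi_score) else -math.inf
        return (q, -g, r.gene)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in sorted(results, key=key):
            fh.write(
                "\t".join(
                    [
                        r.gene,
                        str(r.n_guides),
                        _fmt(r.gi_score),
                        _fmt(r.mhg_stat),
                        _fmt(r.pvalue),
                        _fmt(r.qvalue),
                        r.direction if r.direction else "NA",
                        r.tier,
                    ]
                )
                + "\n"
            )


def read_gene_results(path) -> list[GeneInteraction]:
    """Read back a gene-results TSV written by :func:`write_gene_results`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene results missing columns {missing}")

    def num(s: str) -> float:
        return math.nan if s == "NA" else float(s)

    out = []
    for _, row in df.iterrows():
        pv = num(row["pvalue"])
        out.append(
            GeneInteraction(
                gene=row["gene"],
                n_guides=int(row["n_guides"]),
                gi_score=num(row["gi_score"]),
                mhg_stat=num(row["mhg_stat"]),
                pvalue=pv,
                qvalue=num(row["qvalue"]),
                direction=None if row["direction"] == "NA" else row["direction"],
                tier=row["tier"],
                tested=not math.isnan(pv),
            )
        )
    return out


def write_count_table(table: CountTable, counts_path, samples_path=None) -> None:
    """Write a count table (and optionally its sample metadata) as TSV."""
    df = table.counts.copy()
    if table.stage == RAW:
        df = df.astype(np.int64)
        df.to_csv(counts_path, sep="\t")
    else:
        df.to_csv(counts_path, sep="\t", float_format="%.12g")
    if samples_path is not None:
        meta = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in table.samples],
                "background": [s.background for s in table.samples],
                "timepoint": [s.timepoint for s in table.samples],
                "replicate": [s.replicate for s in table.samples],
            }
        )
        meta.to_csv(samples_path, sep="\t", index=False)


def write_guide_annotation(annotation: GuideAnnotation, path) -> None:
    f = annotation.frame
    out = pd.DataFrame(
        {
            "guide_id": f["guide_id"],
            "target_gene": f["target_gene"].fillna(""),
            "is_control": f["is_control"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False)


_FITNESS_COLUMNS = [
    "guide_id",
    "background",
    "norm_start",
    "norm_end",
    "log2fc_raw",
    "log2fc_centered",
    "passed_filter",
]


def write_fitness_table(fitness: pd.DataFrame, path) -> None:
    """Write the per-guide, per-background fitness table as TSV."""
    out = fitness[_FITNESS_COLUMNS].copy()
    out["passed_filter"] = out["passed_filter"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_fitness_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "background": str})
    missing = [c for c in _FITNESS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"fitness table missing columns {missing}")
    df["passed_filter"] = df["passed_filter"].astype(bool)
    return df
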