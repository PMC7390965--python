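"""Gene-level CDS counting, housekeeping-gene normalization and naive TE.

The counting rule is P-site based: a read contributes to its gene iff
its 5' end shifted by the P-site offset falls inside the CDS (offset 0
for RNA-seq reads).  Libraries are made comparable by scaling to a
housekeeping reference gene (actin in the original design): the size
factor of library j is its reference count divided by the geometric
mean of the reference counts over all libraries, so normalized
reference values are equal across libraries and the factors multiply
to 1.  Size factors are exported for use as offsets by the Bayesian
model, which sees raw counts.

Translation efficiency (TE) is the ratio of normalized RPF to
normalized RNA counts; fold changes between time points use
replicate-averaged normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transcripts import ReadRecord, TranscriptModel, model_index

SAMPLE_COLUMNS = ["assay", "time", "replicate"]


class UnknownTranscriptError(KeyError):
    def __init__(self, missing: Sequence[str]):
        self.missing = sorted(set(missing))
        super().__init__(f"reads reference unknown transcripts: {self.missing[:10]}")


@dataclass
class CountMatrix:
    """Gene x library integer counts with per-library metadata.

    ``samples`` is indexed by library id with columns assay ('rpf' or
    'rna'), time and replicate; ``size_factors`` is set by
    :func:`reference_normalize`.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"libraries without metadata: {sorted(missing)}")
        extra = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if extra:
            raise ValueError(f"sample sheet missing columns: {sorted(extra)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        keys = self.samples.loc[list(self.counts.columns), SAMPLE_COLUMNS]
        if keys.duplicated().any():
            raise ValueError("(assay, time, replicate) must be unique per library")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> pd.Index:
        return self.counts.columns

    def libs_where(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.counts.columns)
        meta = self.samples.loc[list(self.counts.columns)]
        for key, val in criteria.items():
            mask &= meta[key] == val
        return list(mask.index[mask])

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not set; run reference_normalize first")
        return self.counts / self.size_factors.reindex(self.counts.columns)

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path | None = None) -> None:
        self.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        if samples_path is not None:
            self.samples.rename_axis("library_id").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        samples_path: str | Path,
        size_factors_path: str | Path | None = None,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        sf = None
        if size_factors_path is not None:
            sf = pd.read_csv(size_factors_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts, samples, sf)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_cds_reads(
    reads: Iterable[ReadRecord],
    models: Sequence[TranscriptModel],
    offset: int,
    assay: str = "rpf",
) -> pd.Series:
    """Per-gene count of reads whose P-site (5' end + offset) is in the CDS.

    ``offset`` should be the estimated P-site offset for RPF libraries
    and 0 for RNA libraries.  Transcript-level tallies are summed to the
    gene level.  Every gene in ``models`` appears in the output, with 0
    where no read lands in its CDS.
    """
    idx = model_index(models)
    per_gene: dict[str, int] = {m.gene_id: 0 for m in models}
    missing = []
    for r in reads:
        m = idx.get(r.transcript_id)
        if m is None:
            missing.append(r.transcript_id)
            continue
        p = r.five_prime_pos + offset
        if m.cds_start <= p < m.cds_end:
            per_gene[m.gene_id] += 1
    if missing:
        raise UnknownTranscriptError(missing)
    out = pd.Series(per_gene, name=assay, dtype=int)
    out.index.name = "gene_id"
    return out


def build_count_matrix(
    reads_by_library: Mapping[str, Iterable[ReadRecord]],
    models: Sequence[TranscriptModel],
    samples: pd.DataFrame,
    offsets: Mapping[str, int],
) -> CountMatrix:
    """Assemble a CountMatrix by CDS-counting each library's reads."""
    cols = {}
    for lib, reads in reads_by_library.items():
        assay = samples.loc[lib, "assay"]
        cols[lib] = count_cds_reads(reads, models, offsets[lib], assay=assay)
    return CountMatrix(pd.DataFrame(cols), samples)


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def drop_all_zero_genes(cm: CountMatrix) -> CountMatrix:
    """Remove genes with zero count in every library; idempotent."""
    keep = cm.counts.sum(axis=1) > 0
    sf = None if cm.size_factors is None else cm.size_factors.copy()
    return CountMatrix(cm.counts.loc[keep].copy(), cm.samples, sf)


def reference_normalize(cm: CountMatrix, ref_gene: str) -> CountMatrix:
    """Scale libraries to a housekeeping reference gene.

    size_factor_j = ref_count_j / geometric_mean(ref counts); normalized
    value = count / size_factor, so the reference gene's normalized
    values are equal in every library.
    """
    if ref_gene not in cm.counts.index:
        raise ValueError(f"reference gene {ref_gene!r} absent from count matrix")
    ref = cm.counts.loc[ref_gene].astype(float)
    zero_libs = list(ref.index[ref <= 0])
    if zero_libs:
        raise ValueError(
            f"reference gene {ref_gene!r} has zero count in libraries: {zero_libs}"
        )
    geo = float(np.exp(np.mean(np.log(ref))))
    sf = ref / geo
    sf.name = "size_factor"
    return CountMatrix(cm.counts.copy(), cm.samples, sf)


# ---------------------------------------------------------------------------
# Translation efficiency
# ---------------------------------------------------------------------------

def _paired_libs(cm: CountMatrix, time, rep) -> tuple[str, str]:
    rpf = cm.libs_where(assay="rpf", time=time, replicate=rep)
    rna = cm.libs_where(assay="rna", time=time, replicate=rep)
    if len(rpf) != 1 or len(rna) != 1:
        raise ValueError(f"no matched rpf/rna pair for time={time}, replicate={rep}")
    return rpf[0], rna[0]


def translation_efficiency(cm: CountMatrix, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-gene TE (normalized RPF / normalized RNA) for each (time, replicate).

    Columns are a MultiIndex (time, replicate).  Genes with zero RNA in
    a pair get NaN there (flagged missing) unless a pseudocount is
    supplied.
    """
    norm = cm.normalized()
    meta = cm.samples.loc[list(cm.libraries)]
    pairs = sorted(
        {(t, r) for t, r in zip(meta["time"], meta["replicate"])},
        key=lambda p: (p[0], p[1]),
    )
    out = {}
    for t, r in pairs:
        rpf_lib, rna_lib = _paired_libs(cm, t, r)
        rna = norm[rna_lib] + pseudocount
        rpf = norm[rpf_lib] + pseudocount
        out[(t, r)] = (rpf / rna).where(rna > 0)
    te = pd.DataFrame(out)
    te.columns = pd.MultiIndex.from_tuples(out.keys(), names=["time", "replicate"])
    return te


def _time_means(cm: CountMatrix, assay: str, time) -> pd.Series:
    libs = cm.libs_where(assay=assay, time=time)
    if not libs:
        raise ValueError(f"no {assay} libraries at time {time}")
    return cm.normalized()[libs].mean(axis=1)


def te_by_time(cm: CountMatrix, time) -> pd.Series:
    """Replicate-averaged TE at one time point (NaN where RNA mean is 0)."""
    rna = _time_means(cm, "rna", time)
    rpf = _time_means(cm, "rpf", time)
    return (rpf / rna).where(rna > 0)


def log2_fold_change(cm: CountMatrix, gene: str, quantity: str, t1, t2) -> float:
    """log2 of the replicate-averaged normalized ratio t2 / t1.

    ``quantity`` is 'rna', 'rpf' or 'te'; undefined ratios (zero or
    missing denominators) come back as NaN.
    """
    table = fold_change_table(cm, t1, t2)
    col = {"rna": "rna_l2fc", "rpf": "rpf_l2fc", "te": "te_l2fc"}[quantity]
    if gene not in table.index:
        raise KeyError(f"gene {gene!r} not in count matrix")
    return float(table.loc[gene, col])


def fold_change_table(cm: CountMatrix, t1, t2) -> pd.DataFrame:
    """Per-gene log2 fold changes of RNA, RPF and TE between two times.

    Columns: rna_l2fc, rpf_l2fc, te_l2fc, te_t1, te_t2, flags.  ``flags``
    marks genes whose TE is undefined at either time (zero RNA).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        rna1, rna2 = _time_means(cm, "rna", t1), _time_means(cm, "rna", t2)
        rpf1, rpf2 = _time_means(cm, "rpf", t1), _time_means(cm, "rpf", t2)
        te1, te2 = te_by_time(cm, t1), te_by_time(cm, t2)
        out = pd.DataFrame(
            {
                "rna_l2fc": np.log2(rna2 / rna1),
                "rpf_l2fc": np.log2(rpf2 / rpf1),
                "te_l2fc": np.log2(te2 / te1),
                "te_t1": te1,
                "te_t2": te2,
            }
        )
    out["flags"] = np.where(te1.isna() | te2.isna(), "te_undefined", "")
    out.index.name = "gene_id"
    return out
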