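"""Transcript models and aligned-read records in transcript coordinates.

All coordinates are 0-based, half-open and relative to the transcript 5'
end.  A transcript is partitioned into 5'UTR | CDS | 3'UTR; ``cds_start``
is the first nucleotide of the start codon (== ``utr5_len``) and
``cds_end`` the position one past the stop codon.  The stop-codon anchor
used by metagene analysis is the first nucleotide of the stop codon,
``cds_end - 3``.

Reads are stored as (transcript_id, five_prime_pos, length) triples: the
5' end position is the quantity that carries the ribosome-profiling
signal (P-site offset, triplet periodicity), so it is the atom of QC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class TranscriptModel:
    """UTR5/CDS/UTR3 geometry of one transcript, in transcript coordinates."""

    gene_id: str
    transcript_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if self.cds_len <= 0 or self.cds_len % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: cds_len must be a positive multiple of 3, "
                f"got {self.cds_len}"
            )
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.transcript_id}: UTR lengths must be >= 0")

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_start(self) -> int:
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        return self.utr5_len + self.cds_len

    @property
    def stop_codon_start(self) -> int:
        return self.cds_end - 3


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read: transcript, 0-based 5'-end position, length (nt)."""

    transcript_id: str
    five_prime_pos: int
    length: int

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0:
            raise ValueError("five_prime_pos must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be positive")


# ---------------------------------------------------------------------------
# IO: 5-column TSV and BED12 for transcript models; TSV and BED6 for reads
# ---------------------------------------------------------------------------

MODEL_COLUMNS = ["gene_id", "transcript_id", "utr5_len", "cds_len", "utr3_len"]
READ_COLUMNS = ["transcript_id", "five_prime_pos", "length"]


def models_to_frame(models: Iterable[TranscriptModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.gene_id, m.transcript_id, m.utr5_len, m.cds_len, m.utr3_len) for m in models],
        columns=MODEL_COLUMNS,
    )


def write_models_tsv(models: Iterable[TranscriptModel], path: str | Path) -> None:
    models_to_frame(models).to_csv(path, sep="\t", index=False)


def read_models_tsv(path: str | Path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    missing = set(MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transcript model table missing columns: {sorted(missing)}")
    return [
        TranscriptModel(r.gene_id, r.transcript_id, int(r.utr5_len), int(r.cds_len), int(r.utr3_len))
        for r in df.itertuples(index=False)
    ]


def write_models_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """BED12 with one record per transcript; the transcript is its own contig.

    thickStart/thickEnd delimit the CDS, the single block spans the whole
    transcript.
    """
    with open(path, "w") as fh:
        for m in models:
            fields = [
                m.transcript_id, 0, m.length, m.gene_id, 0, "+",
                m.cds_start, m.cds_end, "0", 1, f"{m.length},", "0,",
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_models_bed12(path: str | Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError("BED12 transcript models need at least 8 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else chrom
            thick_start, thick_end = int(f[6]), int(f[7])
            models.append(
                TranscriptModel(
                    gene_id=name,
                    transcript_id=chrom,
                    utr5_len=thick_start - start,
                    cds_len=thick_end - thick_start,
                    utr3_len=end - thick_end,
                )
            )
    return models


def reads_to_frame(reads: Iterable[ReadRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.transcript_id, r.five_prime_pos, r.length) for r in reads],
        columns=READ_COLUMNS,
    )


def write_reads_tsv(reads: Iterable[ReadRecord], path: str | Path) -> None:
    reads_to_frame(reads).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | Path) -> list[ReadRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    return [
        ReadRecord(r.transcript_id, int(r.five_prime_pos), int(r.length))
        for r in df.itertuples(index=False)
    ]


def write_reads_bed6(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """BED6; 5' end = start because all transcript-coordinate reads are + strand."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(
                f"{r.transcript_id}\t{r.five_prime_pos}\t{r.five_prime_pos + r.length}"
                f"\tread{i}\t0\t+\n"
            )


def read_reads_bed6(path: str | Path) -> list[ReadRecord]:
    reads = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            reads.append(ReadRecord(f[0], start, end - start))
    return reads


def model_index(models: Sequence[TranscriptModel]) -> dict[str, TranscriptModel]:
    return {m.transcript_id: m for m in models}
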