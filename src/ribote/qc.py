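"""Quality control for ribosome-profiling reads.

The diagnostics mirror what a profiling experiment must show before its
counts are trusted:

a. footprint length distributions (~30 nt mode for RPFs);
b. high Pearson correlation between biological replicates;
c. reads mapping predominantly to the CDS, minimally to the UTRs;
d. triplet periodicity of RPF 5' ends along the CDS (absent in RNA-seq);
e. a fixed P-site offset (5' ends ~13 nt upstream of start codons);
f. the out-of-frame cleavage peak just upstream of stop codons.

All computations run on (transcript_id, five_prime_pos, length) records
against transcript geometries; coordinates are 0-based and transcript
relative, so "13 nt upstream of the start codon" means
five_prime_pos == cds_start - 13.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import CountMatrix, UnknownTranscriptError
from .transcripts import ReadRecord, TranscriptModel, model_index

# search window for the 5'-end -> P-site distance; brackets known
# eukaryotic offsets (12-14 nt)
OFFSET_SEARCH_RANGE = range(8, 19)


# ---------------------------------------------------------------------------
# Length filtering and distribution
# ---------------------------------------------------------------------------

def filter_by_length(
    reads: Sequence[ReadRecord], min_len: int, max_len: int
) -> list[ReadRecord]:
    """Keep reads with min_len <= length <= max_len (inclusive); idempotent."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    return [r for r in reads if min_len <= r.length <= max_len]


def length_distribution(reads: Iterable[ReadRecord]) -> pd.Series:
    """Histogram length -> count; lengths absent inside the observed span are 0."""
    lengths = [r.length for r in reads]
    if not lengths:
        return pd.Series(dtype=int, name="count")
    counts = pd.Series(lengths).value_counts()
    span = range(counts.index.min(), counts.index.max() + 1)
    return counts.reindex(span, fill_value=0).rename("count").rename_axis("length")


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------

def region_fractions(
    reads: Sequence[ReadRecord],
    models: Sequence[TranscriptModel],
    offset: int = 0,
) -> tuple[dict[str, float], dict[str, int]]:
    """Fraction of reads whose P-site (5' end + offset) falls in UTR5/CDS/UTR3.

    Returns (fractions, counts); fractions sum to 1 over assigned reads.
    P-sites clamped past the transcript end count as UTR3.
    """
    idx = model_index(models)
    counts = {"utr5": 0, "cds": 0, "utr3": 0}
    missing = []
    for r in reads:
        m = idx.get(r.transcript_id)
        if m is None:
            missing.append(r.transcript_id)
            continue
        p = r.five_prime_pos + offset
        if p < m.cds_start:
            counts["utr5"] += 1
        elif p < m.cds_end:
            counts["cds"] += 1
        else:
            counts["utr3"] += 1
    if missing:
        raise UnknownTranscriptError(missing)
    total = sum(counts.values())
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return fractions, counts


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Mean 5'-end counts per position relative to a start/stop anchor.

    Positions run over ``window`` = [left, right] inclusive, relative to
    the anchor (first nt of the start codon, or first nt of the stop
    codon).  ``mean_counts[i]`` is the mean count at position i over
    transcripts with at least one read in the window;
    ``frame_of_position`` annotates each position with its codon frame
    relative to the CDS start.  ``n_transcripts`` is the number of
    transcripts entering the mean.
    """

    anchor: str
    positions: np.ndarray
    mean_counts: np.ndarray
    frame_of_position: np.ndarray
    n_transcripts: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean_count": self.mean_counts,
                "frame": self.frame_of_position,
            }
        )

    def peak(self) -> tuple[int, int]:
        """(position, frame) of the maximum mean count; diagnostic for the
        out-of-frame peak upstream of stop codons."""
        i = int(np.argmax(self.mean_counts))
        return int(self.positions[i]), int(self.frame_of_position[i])


def metagene_profile(
    reads: Sequence[ReadRecord],
    models: Sequence[TranscriptModel],
    anchor: str = "start",
    window: tuple[int, int] = (-30, 60),
    lengths: Sequence[int] | None = None,
) -> MetageneProfile:
    """Average read 5'-end counts across transcripts around a shared anchor.

    A transcript contributes iff it has >= 1 read (of the selected
    lengths) inside the window; no per-transcript depth normalization is
    applied, so values are mean raw counts.
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    left, right = window
    if left > right:
        raise ValueError("window must satisfy left <= right")
    if not (left <= 0 <= right):
        raise ValueError("window must cover the anchor (position 0)")
    idx = model_index(models)
    width = right - left + 1
    keep_len = None if lengths is None else set(lengths)

    per_tx: dict[str, np.ndarray] = {}
    for r in reads:
        if keep_len is not None and r.length not in keep_len:
            continue
        m = idx.get(r.transcript_id)
        if m is None:
            continue
        anchor_pos = m.cds_start if anchor == "start" else m.stop_codon_start
        rel = r.five_prime_pos - anchor_pos
        if left <= rel <= right:
            per_tx.setdefault(r.transcript_id, np.zeros(width))[rel - left] += 1

    positions = np.arange(left, right + 1)
    if not per_tx:
        frames = _window_frames(positions, anchor, models)
        return MetageneProfile(anchor, positions, np.zeros(width), frames, 0)
    mean = np.mean(list(per_tx.values()), axis=0)
    frames = _window_frames(positions, anchor, models)
    return MetageneProfile(anchor, positions, mean, frames, len(per_tx))


def _window_frames(
    positions: np.ndarray, anchor: str, models: Sequence[TranscriptModel]
) -> np.ndarray:
    # frame relative to CDS start; for the stop anchor the anchor itself is
    # the first nt of the stop codon, which is in frame 0 (cds_len % 3 == 0)
    return positions % 3


# ---------------------------------------------------------------------------
# Triplet periodicity
# ---------------------------------------------------------------------------

def frame_fractions(
    reads: Sequence[ReadRecord],
    models: Sequence[TranscriptModel],
    offset: int = 0,
) -> tuple[tuple[float, float, float], float]:
    """Codon-frame occupancy of P-sites inside CDSs and a chi-square vs uniform.

    frame = (five_prime_pos + offset - cds_start) mod 3, restricted to
    reads whose P-site lies inside the CDS.  The statistic is
    sum_i (O_i - N/3)^2 / (N/3); a large value signals triplet
    periodicity, as expected for footprints but not RNA fragments.
    """
    idx = model_index(models)
    obs = np.zeros(3, dtype=int)
    for r in reads:
        m = idx.get(r.transcript_id)
        if m is None:
            continue
        p = r.five_prime_pos + offset
        if m.cds_start <= p < m.cds_end:
            obs[(p - m.cds_start) % 3] += 1
    n = int(obs.sum())
    if n == 0:
        raise ValueError("no reads with a CDS-internal P-site")
    expected = n / 3.0
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    f = obs / n
    return (float(f[0]), float(f[1]), float(f[2])), chi2


def periodicity_pvalue(chi2: float) -> float:
    """p-value of the 2-df chi-square test against a uniform frame split."""
    from scipy import stats

    return float(stats.chi2.sf(chi2, df=2))


# ---------------------------------------------------------------------------
# P-site offset estimation
# ---------------------------------------------------------------------------

def estimate_psite_offset(
    reads: Sequence[ReadRecord],
    models: Sequence[TranscriptModel],
    per_length: bool = True,
) -> dict[int, int] | int:
    """Distance from RPF 5' ends to the start codon, by read length.

    For each length, counts reads with five_prime_pos == cds_start - d
    aggregated over transcripts for d in [8, 18] and returns the argmax
    (ties towards smaller d).  With per_length=False all lengths are
    pooled and a single offset is returned.
    """
    idx = model_index(models)
    tallies: dict[int, np.ndarray] = {}
    offsets = np.array(list(OFFSET_SEARCH_RANGE))
    for r in reads:
        m = idx.get(r.transcript_id)
        if m is None:
            continue
        d = m.cds_start - r.five_prime_pos
        if d in OFFSET_SEARCH_RANGE:
            key = r.length if per_length else 0
            tallies.setdefault(key, np.zeros(len(offsets), dtype=int))[
                d - OFFSET_SEARCH_RANGE.start
            ] += 1
    if not tallies:
        raise ValueError(
            "no reads with 5' ends in the start-codon offset window [8, 18]"
        )
    # np.argmax returns the first (smallest-d) maximiser: the tie-break rule
    result = {k: int(offsets[int(np.argmax(v))]) for k, v in tallies.items()}
    if per_length:
        return dict(sorted(result.items()))
    return result[0]


# ---------------------------------------------------------------------------
# Replicate correlation
# ---------------------------------------------------------------------------

def replicate_correlation(cm: CountMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of log(count + 1) across libraries.

    Zero-variance libraries yield NaN entries (flagged undefined).
    Apply the all-zero gene filter first.
    """
    if len(cm.libraries) < 2:
        raise ValueError("need at least two libraries")
    logged = np.log1p(cm.counts.astype(float))
    return logged.corr(method="pearson")


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Bundle of the QC diagnostics for one RPF library (+ optional RNA)."""

    length_hist: pd.Series
    frame_fractions: tuple[float, float, float]
    frame_chi2: float
    frame_pvalue: float
    offsets_by_length: dict[int, int]
    region_fractions: dict[str, float]
    stop_peak: tuple[int, int]

    def to_tables(self) -> dict[str, pd.DataFrame]:
        return {
            "length_hist": self.length_hist.reset_index(),
            "frames": pd.DataFrame(
                {
                    "frame": [0, 1, 2],
                    "fraction": list(self.frame_fractions),
                }
            ),
            "offsets": pd.DataFrame(
                sorted(self.offsets_by_length.items()),
                columns=["length", "psite_offset"],
            ),
            "regions": pd.DataFrame(
                sorted(self.region_fractions.items()), columns=["region", "fraction"]
            ),
            "summary": pd.DataFrame(
                {
                    "metric": [
                        "frame_chi2",
                        "frame_pvalue",
                        "stop_peak_position",
                        "stop_peak_frame",
                    ],
                    "value": [
                        self.frame_chi2,
                        self.frame_pvalue,
                        self.stop_peak[0],
                        self.stop_peak[1],
                    ],
                }
            ),
        }


def qc_report(
    reads: Sequence[ReadRecord],
    models: Sequence[TranscriptModel],
    offset: int | None = None,
    stop_window: tuple[int, int] = (-30, 6),
) -> QCReport:
    """Run the full RPF QC battery on one library.

    When ``offset`` is None the dominant-length P-site offset is
    estimated from the data and used for frame and region assignment.
    """
    hist = length_distribution(reads)
    offsets = estimate_psite_offset(reads, models, per_length=True)
    if offset is None:
        dominant = int(hist.idxmax())
        offset = offsets.get(dominant, next(iter(offsets.values())))
    fracs, chi2 = frame_fractions(reads, models, offset=offset)
    regions, _ = region_fractions(reads, models, offset=offset)
    stop_prof = metagene_profile(reads, models, anchor="stop", window=stop_window)
    return QCReport(
        length_hist=hist,
        frame_fractions=fracs,
        frame_chi2=chi2,
        frame_pvalue=periodicity_pvalue(chi2),
        offsets_by_length=offsets,
        region_fractions=regions,
        stop_peak=stop_prof.peak(),
    )
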