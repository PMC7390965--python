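"""Synthetic ribosome-profiling experiment generator.

Emulates a tunicamycin time-course design: two biological replicates at
each of several time points, each sample sequenced as a paired ribo-seq
(RPF) and RNA-seq library.  Gene-level counts follow the same generative
model the inference module fits:

* RNA counts are Poisson with mean  s_j * exp(eta_tr) * mu_g * rho_g(t);
* RPF counts are zero-inflated Poisson with an extra translation-
  efficiency factor delta_g applied at the contrast (last) time point,
  and a global excess-zero probability pi_zero;
* a fraction 1 - p0 of genes carry a real TE change, with delta drawn
  from a Gamma slab so changes go in both directions; the rest have
  delta = 1 exactly (the spike).

Positional reads emulate the footprinting signal: RPF 5' ends sit a
fixed P-site offset upstream of CDS-internal codons with a triplet-
periodic frame preference; RNA fragments are placed uniformly along the
transcript.  Ground truth is returned alongside every simulation so
downstream QC, counting and model recovery are testable without any
external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .transcripts import (
    ReadRecord,
    TranscriptModel,
    write_models_bed12,
    write_models_tsv,
    write_reads_bed6,
    write_reads_tsv,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the study design: 2 biological replicates x 3 time
    points (0/6/12 hr) x 2 assays, ~30 nt footprints with a 13 nt P-site
    offset and a dominant in-frame fraction, a modest global excess-zero
    probability for RPF counts, and a spike-and-slab TE change (80% of
    genes unchanged; Gamma(2, 2) fold changes otherwise).
    """

    n_genes: int = 2000
    utr5_range: tuple[int, int] = (30, 150)
    cds_codon_range: tuple[int, int] = (100, 500)
    utr3_range: tuple[int, int] = (50, 250)
    times: tuple[int, ...] = (0, 6, 12)
    n_reps: int = 2
    lib_depth: float = 1_000_000.0
    mu_log_mean: float = 4.0          # log-scale location of baseline abundance
    mu_log_sd: float = 1.5
    p_change_rna: float = 0.3         # fraction of genes with an RNA fold change
    rna_lfc_sd: float = 1.0           # SD of log RNA fold changes (natural log)
    p0: float = 0.8                   # prior probability of NO TE change
    gamma_shape: float = 2.0          # slab for TE fold changes of changed genes
    gamma_rate: float = 2.0
    pi_zero: float = 0.1              # RPF zero-inflation probability
    sigma_pair: float = 0.1           # SD of per-(time, rep) pairing effect (log)
    lib_size_sd: float = 0.2          # log-SD of per-library depth factors
    frame_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    psite_offset: int = 13
    rpf_len_probs: dict[int, float] = field(
        default_factory=lambda: {
            27: 0.04, 28: 0.08, 29: 0.15, 30: 0.25, 31: 0.17,
            32: 0.13, 33: 0.09, 34: 0.06, 35: 0.03,
        }
    )
    rna_len_range: tuple[int, int] = (25, 40)
    start_codon_boost: float = 4.0    # initiation-pause occupancy of codon 0
    include_reference: bool = True    # emit an actin-like housekeeping gene
    ref_gene_id: str = "ZmActin2"
    ref_frac: float = 0.02            # fraction of library depth from the reference
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for name in ("utr5_range", "cds_codon_range", "utr3_range", "rna_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigError(f"{name} must be a non-empty non-negative range")
        if self.cds_codon_range[0] < 1:
            raise ConfigError("cds_codon_range must be >= 1 codon")
        if len(self.times) < 1:
            raise ConfigError("need at least one time point")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        fp = np.asarray(self.frame_probs, dtype=float)
        if fp.shape != (3,) or abs(fp.sum() - 1.0) > 1e-12 or (fp < 0).any():
            raise ConfigError("frame_probs must be 3 non-negative values summing to 1")
        lp = np.asarray(list(self.rpf_len_probs.values()), dtype=float)
        if abs(lp.sum() - 1.0) > 1e-9 or (lp < 0).any():
            raise ConfigError("rpf_len_probs must sum to 1")
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.pi_zero <= 1.0):
            raise ConfigError("p0 and pi_zero must lie in [0, 1]")
        if not (0.0 <= self.p_change_rna <= 1.0):
            raise ConfigError("p_change_rna must lie in [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ConfigError("gamma_shape and gamma_rate must be > 0")
        if self.sigma_pair < 0 or self.lib_size_sd < 0:
            raise ConfigError("sigma_pair and lib_size_sd must be >= 0")
        if self.lib_depth < 0:
            raise ConfigError("lib_depth must be >= 0")
        if not (0.0 < self.ref_frac < 1.0):
            raise ConfigError("ref_frac must lie in (0, 1)")
        if self.start_codon_boost < 1.0:
            raise ConfigError("start_codon_boost must be >= 1")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``genes`` has one row per gene: relative baseline abundance weight
    mu (scaled to expected counts via the library depth), the RNA fold
    change at the last time point rho, the TE-change indicator z and TE
    fold change delta (delta == 1 exactly when z == 0).  ``rho_by_time`` holds the
    per-time RNA fold factors (geometric interpolation towards rho).
    ``libraries`` has one row per library with its size factor and the
    pairing effect shared by the paired RPF/RNA libraries of a sample.
    ``expected`` is the Poisson/ZIP rate matrix lambda (genes x libs).
    """

    genes: pd.DataFrame
    rho_by_time: pd.DataFrame
    libraries: pd.DataFrame
    expected: pd.DataFrame

    def validate(self) -> None:
        g = self.genes
        spike = g["z"].to_numpy() == 0
        if not np.all(g.loc[spike, "delta"].to_numpy() == 1.0):
            raise AssertionError("genes with z == 0 must have delta == 1 exactly")
        if (g[["mu", "rho", "delta"]].to_numpy() <= 0).any():
            raise AssertionError("mu, rho, delta must be positive")


def library_id(assay: str, time: int, rep: int) -> str:
    return f"{assay}_t{time}_r{rep}"


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    """One row per library: (library_id, assay, time, replicate)."""
    rows = [
        (library_id(assay, t, r), assay, t, r)
        for assay in ("rpf", "rna")
        for t in config.times
        for r in range(1, config.n_reps + 1)
    ]
    return pd.DataFrame(rows, columns=["library_id", "assay", "time", "replicate"])


# ---------------------------------------------------------------------------
# Transcriptome geometry
# ---------------------------------------------------------------------------

def make_transcriptome(config: SimConfig) -> list[TranscriptModel]:
    """Draw per-gene UTR and CDS lengths; CDS lengths are whole codons."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = _gene_ids(config)
    utr5 = rng.integers(config.utr5_range[0], config.utr5_range[1] + 1, size=len(names))
    codons = rng.integers(
        config.cds_codon_range[0], config.cds_codon_range[1] + 1, size=len(names)
    )
    utr3 = rng.integers(config.utr3_range[0], config.utr3_range[1] + 1, size=len(names))
    return [
        TranscriptModel(g, f"{g}_T001", int(u5), int(3 * nc), int(u3))
        for g, u5, nc, u3 in zip(names, utr5, codons, utr3)
    ]


def _gene_ids(config: SimConfig) -> list[str]:
    names = [f"gene{i:05d}" for i in range(config.n_genes)]
    if config.include_reference:
        names.append(config.ref_gene_id)
    return names


# ---------------------------------------------------------------------------
# Gene-level counts
# ---------------------------------------------------------------------------

def _draw_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    names = _gene_ids(config)
    n = len(names)
    mu = rng.lognormal(config.mu_log_mean, config.mu_log_sd, size=n)
    changed_rna = rng.random(n) < config.p_change_rna
    log_rho = np.where(changed_rna, rng.normal(0.0, config.rna_lfc_sd, size=n), 0.0)
    z = (rng.random(n) >= config.p0).astype(int)
    delta = np.where(
        z == 1, rng.gamma(config.gamma_shape, 1.0 / config.gamma_rate, size=n), 1.0
    )
    if config.include_reference:
        # the housekeeping anchor: fixed fraction of depth, no change at all
        log_rho[-1] = 0.0
        z[-1] = 0
        delta[-1] = 1.0
        mu[-1] = config.ref_frac / (1.0 - config.ref_frac) * mu[:-1].sum()
    # mu are relative abundance weights; depth_scale converts them to
    # expected baseline counts so library totals equal lib_depth exactly
    depth_scale = config.lib_depth / mu.sum()

    # geometric interpolation of RNA induction from baseline to last time
    times = list(config.times)
    fracs = (
        np.linspace(0.0, 1.0, len(times))
        if len(times) > 1
        else np.array([0.0])
    )
    rho_by_time = pd.DataFrame(
        {t: np.exp(log_rho * f) for t, f in zip(times, fracs)}, index=names
    )

    sheet = sample_sheet(config)
    eta_keys = [(t, r) for t in times for r in range(1, config.n_reps + 1)]
    eta = {k: rng.normal(0.0, config.sigma_pair) for k in eta_keys}
    size = {
        lid: float(np.exp(rng.normal(0.0, config.lib_size_sd)))
        for lid in sheet["library_id"]
    }
    libraries = sheet.set_index("library_id").copy()
    libraries["size_factor"] = [size[l] for l in libraries.index]
    libraries["pairing_effect"] = [
        eta[(t, r)] for t, r in zip(libraries["time"], libraries["replicate"])
    ]

    contrast_time = times[-1]
    lam = np.empty((n, len(libraries)))
    for j, (lid, row) in enumerate(libraries.iterrows()):
        rate = depth_scale * mu * rho_by_time[row["time"]].to_numpy()
        if row["assay"] == "rpf" and row["time"] == contrast_time:
            rate = rate * delta
        lam[:, j] = size[lid] * np.exp(eta[(row["time"], row["replicate"])]) * rate
    expected = pd.DataFrame(lam, index=names, columns=libraries.index)

    genes = pd.DataFrame(
        {"mu": mu, "rho": np.exp(log_rho), "z": z, "delta": delta}, index=names
    )
    truth = SimTruth(genes, rho_by_time, libraries.reset_index(), expected)
    truth.validate()
    return truth


def simulate_counts(config: SimConfig):
    """Draw a gene x library count matrix and its ground truth.

    Returns a :class:`ribote.counts.CountMatrix` and a :class:`SimTruth`.
    RNA counts are Poisson draws from the expected-rate matrix; RPF
    counts are the same rates pushed through zero inflation.
    """
    from .counts import CountMatrix

    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    lam = truth.expected.to_numpy()
    counts = rng.poisson(lam)
    is_rpf = (truth.libraries["assay"] == "rpf").to_numpy()
    dropout = rng.random(lam.shape) < config.pi_zero
    if config.include_reference:
        # the housekeeping anchor must stay observable in every library
        dropout[-1, :] = False
    counts[:, is_rpf] = np.where(dropout[:, is_rpf], 0, counts[:, is_rpf])
    frame = pd.DataFrame(
        counts, index=truth.expected.index, columns=truth.expected.columns
    )
    cm = CountMatrix(frame, truth.libraries.set_index("library_id"))
    return cm, truth


# ---------------------------------------------------------------------------
# Positional reads
# ---------------------------------------------------------------------------

def simulate_reads(
    config: SimConfig,
    transcriptome: Sequence[TranscriptModel],
    assay: str = "rpf",
    n_reads: int | None = None,
    seed: int | None = None,
) -> list[ReadRecord]:
    """Place read 5' ends on transcripts.

    RPF reads: a CDS codon is chosen on the chosen transcript (uniform
    over elongation codons, with an initiation-pause enrichment of codon
    0), a codon-relative frame is drawn from ``frame_probs``, and the 5' end
    is placed ``psite_offset`` nt upstream of that P-site position (so
    5' end + offset lands in the CDS at the drawn frame).  When the
    5'UTR is shorter than the offset the read is truncated at position 0
    (documented behaviour, not an error).  RNA reads are uniform over
    the whole transcript.  Transcript choice is weighted by a fresh
    draw of baseline abundances.
    """
    config.validate()
    if not transcriptome:
        raise ConfigError("transcriptome must be non-empty")
    if assay not in ("rpf", "rna"):
        raise ValueError("assay must be 'rpf' or 'rna'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(config.lib_depth if n_reads is None else n_reads)
    weights = rng.lognormal(config.mu_log_mean, config.mu_log_sd, size=len(transcriptome))
    weights /= weights.sum()
    tx_idx = rng.choice(len(transcriptome), size=n, p=weights)

    tx_len = np.array([m.length for m in transcriptome])
    cds_start = np.array([m.cds_start for m in transcriptome])
    n_codons = np.array([m.cds_len // 3 for m in transcriptome])

    if assay == "rpf":
        lens = np.array(sorted(config.rpf_len_probs))
        lprobs = np.array([config.rpf_len_probs[l] for l in lens], dtype=float)
        lprobs /= lprobs.sum()
        length = lens[rng.choice(len(lens), size=n, p=lprobs)]
        # ribosomes pause at initiation: codon 0 carries `start_codon_boost`
        # times the occupancy of any elongation codon, which also makes the
        # P-site offset identifiable from the start-codon peak
        nc = n_codons[tx_idx]
        boost = config.start_codon_boost
        p_start = boost / (nc - 1 + boost)
        at_start = rng.random(n) < p_start
        codon = np.where(
            at_start,
            0,
            1 + (rng.random(n) * np.maximum(nc - 1, 1)).astype(int),
        )
        codon = np.minimum(codon, nc - 1)  # single-codon CDS guard
        frame = rng.choice(3, size=n, p=np.asarray(config.frame_probs, dtype=float))
        psite = cds_start[tx_idx] + 3 * codon + frame
        five = psite - config.psite_offset
        five = np.maximum(five, 0)  # truncate when UTR5 shorter than offset
    else:
        lo, hi = config.rna_len_range
        length = rng.integers(lo, hi + 1, size=n)
        five = (rng.random(n) * tx_len[tx_idx]).astype(int)
    # clamp read ends at the transcript 3' end
    length = np.minimum(length, tx_len[tx_idx] - five)
    ids = [transcriptome[i].transcript_id for i in tx_idx]
    return [
        ReadRecord(tid, int(p), int(l)) for tid, p, l in zip(ids, five, length)
    ]


# ---------------------------------------------------------------------------
# On-disk experiment
# ---------------------------------------------------------------------------

def write_experiment(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate one full experiment and write every artefact as TSV/BED.

    Emits transcript models (TSV + BED12), gene-level counts, ground
    truth, the sample sheet, and positional RPF/RNA reads for one
    representative library of each assay.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transcriptome = make_transcriptome(config)
    cm, truth = simulate_counts(config)
    paths = {
        "models_tsv": out / "transcript_models.tsv",
        "models_bed12": out / "transcript_models.bed12",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "truth_genes": out / "truth_genes.tsv",
        "truth_libraries": out / "truth_libraries.tsv",
        "rpf_reads": out / "reads_rpf.tsv",
        "rpf_reads_bed": out / "reads_rpf.bed",
        "rna_reads": out / "reads_rna.tsv",
    }
    write_models_tsv(transcriptome, paths["models_tsv"])
    write_models_bed12(transcriptome, paths["models_bed12"])
    cm.to_tsv(paths["counts"], paths["samples"])
    truth.genes.rename_axis("gene_id").to_csv(paths["truth_genes"], sep="\t")
    truth.libraries.to_csv(paths["truth_libraries"], sep="\t", index=False)
    rpf = simulate_reads(config, transcriptome, assay="rpf", seed=config.seed + 1)
    rna = simulate_reads(config, transcriptome, assay="rna", seed=config.seed + 2)
    write_reads_tsv(rpf, paths["rpf_reads"])
    write_reads_bed6(rpf, paths["rpf_reads_bed"])
    write_reads_tsv(rna, paths["rna_reads"])
    return paths
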