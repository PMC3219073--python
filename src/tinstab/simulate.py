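"""Synthetic exon-array cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* additive log2 probe intensities per gene — gene/sample effect + probe
  affinity + noise — with coherent exon-level deviations (all probes of a
  probe set shifted by +/- delta) injected at a per-sample rate;
* a TIN-positive subset of samples whose injection rate is multiplied and
  whose injected signs are skewed towards skipping;
* splicing-factor genes whose expression decreases with the sample's
  deviation burden;
* exponential survival times whose hazard is multiplied for TIN-positive
  patients, with administrative censoring.

All randomness flows from a single seeded generator, so the same config
and seed reproduce every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .io import ChipDefinition, ValidationError

logger = logging.getLogger("tinstab")

__all__ = [
    "SimulationConfig", "GroundTruth", "SimulatedDataset",
    "generate_chipdef", "generate_intensities", "generate_sf_expression",
    "generate_clinical", "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are desk-scale: ~300 genes x ~8 probe sets x 4 probes x 80
    samples.  Rates and effect sizes place baseline samples near 2% of
    probe sets deviating and TIN-positive samples at ~4.5%, inside the
    per-sample range observed on real exon arrays.
    """

    n_genes: int = 300
    probe_sets_per_gene: tuple[int, int] = (4, 12)   # uniform inclusive bounds
    probes_per_set: int = 4
    n_samples: int = 80
    base_deviation_rate: float = 0.015   # P(injected deviation) per (probe set, sample)
    tin_sample_fraction: float = 0.10
    tin_rate_multiplier: float = 3.0
    skew_ratio: float = 4.0              # skip:inclusion odds for TIN samples
    deviation_delta: float = 1.5         # log2 units
    noise_sigma: float = 0.25            # log2 units
    n_sf_genes: int = 40
    sf_coupling_beta: float = 1.0        # expression drop per SD of deviation burden
    sf_noise_sigma: float = 0.3
    n_null_genes: int = 400              # matched null genes for standalone SF matrices
    hazard_baseline: float = 0.05        # events / year
    hazard_log_hr: float = float(np.log(3.0))
    censor_time: float = 10.0            # years
    background_scale: float = 0.0        # mean of additive exponential background; 0 = off
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_genes", "probes_per_set", "n_samples"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        lo, hi = self.probe_sets_per_gene
        if lo < 1 or hi < lo:
            raise ValidationError("probe_sets_per_gene bounds must satisfy 1 <= lo <= hi")
        for name in ("base_deviation_rate", "tin_sample_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.tin_rate_multiplier < 1:
            raise ValidationError("tin_rate_multiplier must be >= 1")
        if self.censor_time <= 0:
            raise ValidationError("censor_time must be > 0")
        if self.n_sf_genes > self.n_genes:
            raise ValidationError("n_sf_genes cannot exceed n_genes")


@dataclass
class GroundTruth:
    """What was injected, to score recovery against."""

    injected_events: pd.DataFrame        # gene, probe_set, sample, sign
    tin_samples: list[str]
    sf_genes: list[str]
    log_hr: float
    burden: pd.Series                    # injected deviations per sample

    def to_dict(self) -> dict:
        return {
            "injected_events": self.injected_events.to_dict(orient="records"),
            "tin_samples": self.tin_samples,
            "sf_genes": self.sf_genes,
            "log_hr": self.log_hr,
            "burden": {k: int(v) for k, v in self.burden.items()},
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            injected_events=pd.DataFrame(
                d["injected_events"],
                columns=["gene", "probe_set", "sample", "sign"]),
            tin_samples=d["tin_samples"],
            sf_genes=d["sf_genes"],
            log_hr=d["log_hr"],
            burden=pd.Series(d["burden"]),
        )


def generate_chipdef(config: SimulationConfig,
                     rng: np.random.Generator) -> ChipDefinition:
    """Probe -> probe set -> gene hierarchy with per-gene set counts drawn
    uniformly from the configured bounds."""
    lo, hi = config.probe_sets_per_gene
    n_sets = rng.integers(lo, hi + 1, size=config.n_genes)
    rows = []
    for g in range(config.n_genes):
        gene = f"G{g + 1:05d}"
        for j in range(n_sets[g]):
            ps = f"{gene}:PS{j + 1:02d}"
            for k in range(config.probes_per_set):
                rows.append((f"{ps}:P{k + 1}", ps, gene))
    df = pd.DataFrame(rows, columns=["probe_id", "probe_set_id", "gene_id"])
    return ChipDefinition(df)


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def generate_intensities(chipdef: ChipDefinition, config: SimulationConfig,
                         rng: np.random.Generator
                         ) -> tuple[pd.DataFrame, GroundTruth]:
    """Linear-scale probe intensities with injected exon-level deviations.

    Model (log2 scale): c[gene, sample] + p[probe] + delta * Z[set, sample]
    + noise.  Splicing-factor genes' expression level c is negatively
    coupled to the sample's standardized deviation burden.
    """
    samples = _sample_ids(config.n_samples)
    records = chipdef.records
    genes = list(pd.unique(records["gene_id"]))
    sets_df = records.drop_duplicates("probe_set_id")
    set_ids = sets_df["probe_set_id"].to_numpy()
    set_gene = sets_df["gene_id"].to_numpy()
    n_sets, n_samp = len(set_ids), config.n_samples

    n_tin = int(round(config.tin_sample_fraction * n_samp))
    tin_idx = np.sort(rng.choice(n_samp, size=n_tin, replace=False))
    is_tin = np.zeros(n_samp, dtype=bool)
    is_tin[tin_idx] = True

    rate = np.where(is_tin, config.base_deviation_rate * config.tin_rate_multiplier,
                    config.base_deviation_rate)
    if (rate >= 0.5).any():
        warnings.warn("deviation rate >= 0.5: deviations no longer deviate "
                      "from a general pattern", stacklevel=2)
    deviates = rng.random((n_sets, n_samp)) < rate[None, :]
    # TIN samples inject with skewed sign odds; baseline samples 1:1
    p_skip = np.where(is_tin, config.skew_ratio / (1.0 + config.skew_ratio), 0.5)
    sign = np.where(rng.random((n_sets, n_samp)) < p_skip[None, :], -1, 1)
    Z = deviates * sign
    burden = deviates.sum(axis=0)

    sf_genes = genes[:config.n_sf_genes]
    c = rng.normal(8.0, 1.5, size=(len(genes), n_samp))
    if config.n_sf_genes:
        std = burden.std()
        burden_std = (burden - burden.mean()) / std if std > 0 else np.zeros(n_samp)
        a = rng.normal(8.0, 1.0, size=(config.n_sf_genes, 1))
        c[:config.n_sf_genes, :] = (
            a - config.sf_coupling_beta * burden_std[None, :]
            + rng.normal(0.0, config.sf_noise_sigma, size=(config.n_sf_genes, n_samp))
        )

    gene_pos = {g: i for i, g in enumerate(genes)}
    set_pos = {s: i for i, s in enumerate(set_ids)}
    probe_gene_idx = records["gene_id"].map(gene_pos).to_numpy()
    probe_set_idx = records["probe_set_id"].map(set_pos).to_numpy()

    p_effect = rng.normal(0.0, 0.5, size=len(records))
    # center probe affinities within each gene
    p_effect -= pd.Series(p_effect).groupby(probe_gene_idx).transform("mean").to_numpy()

    log2_i = (c[probe_gene_idx, :]
              + p_effect[:, None]
              + config.deviation_delta * Z[probe_set_idx, :]
              + rng.normal(0.0, config.noise_sigma, size=(len(records), n_samp)))
    intensities = np.exp2(log2_i)
    if config.background_scale > 0:
        intensities = intensities + rng.exponential(
            config.background_scale, size=intensities.shape)
    matrix = pd.DataFrame(intensities,
                          index=pd.Index(records["probe_id"], name="probe_id"),
                          columns=samples)

    ev_set, ev_sample = np.nonzero(Z)
    events = pd.DataFrame({
        "gene": set_gene[ev_set],
        "probe_set": set_ids[ev_set],
        "sample": np.array(samples)[ev_sample],
        "sign": np.sign(Z[ev_set, ev_sample]).astype(int),
    })
    truth = GroundTruth(
        injected_events=events,
        tin_samples=[samples[i] for i in tin_idx],
        sf_genes=list(sf_genes),
        log_hr=config.hazard_log_hr,
        burden=pd.Series(burden, index=samples, name="burden"),
    )
    logger.info("simulated %d probes x %d samples; %d injected events, %d TIN samples",
                len(records), n_samp, len(events), n_tin)
    return matrix, truth


def generate_sf_expression(burden: pd.Series, config: SimulationConfig,
                           rng: np.random.Generator,
                           n_null_genes: int | None = None) -> pd.DataFrame:
    """Standalone gene-level expression: coupled SF genes + matched nulls.

    expr[g, s] = a_g - beta * burden_std[s] * coupled[g] + noise.  Rows
    "SF...." are negatively coupled to the standardized burden; rows
    "NULL..." are independent of it.
    """
    if n_null_genes is None:
        n_null_genes = config.n_null_genes
    samples = list(burden.index)
    b = burden.to_numpy(dtype=float)
    std = b.std()
    b_std = (b - b.mean()) / std if std > 0 else np.zeros_like(b)
    n_sf = config.n_sf_genes
    ids = ([f"SF{i + 1:04d}" for i in range(n_sf)]
           + [f"NULL{i + 1:04d}" for i in range(n_null_genes)])
    a = rng.normal(8.0, 1.0, size=(len(ids), 1))
    coupled = np.zeros((len(ids), 1))
    coupled[:n_sf] = 1.0
    expr = (a - config.sf_coupling_beta * coupled * b_std[None, :]
            + rng.normal(0.0, config.sf_noise_sigma, size=(len(ids), len(samples))))
    return pd.DataFrame(expr, index=pd.Index(ids, name="gene_id"), columns=samples)


def generate_clinical(tin_flags: pd.Series, config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Exponential survival with hazard h0 * exp(log_hr) for TIN-positive
    patients, administrative censoring, and independent covariates."""
    samples = list(tin_flags.index)
    n = len(samples)
    flags = tin_flags.to_numpy(dtype=bool)
    hazard = config.hazard_baseline * np.exp(config.hazard_log_hr * flags)
    t_event = rng.exponential(1.0 / hazard)
    time = np.minimum(t_event, config.censor_time)
    event = (t_event <= config.censor_time).astype(int)
    df = pd.DataFrame({
        "time_years": np.round(time, 6),
        "event": event,
        "stage": rng.choice(["II", "III"], size=n, p=[0.55, 0.45]),
        "msi": rng.binomial(1, 0.2, size=n),
        "age": np.round(np.clip(rng.normal(70, 10, size=n), 30, 95), 1),
        "sex": rng.choice(["M", "F"], size=n),
        "location": rng.choice(["right", "left", "rectum"], size=n,
                               p=[0.4, 0.3, 0.3]),
    }, index=pd.Index(samples, name="sample_id"))
    logger.info("simulated clinical: %d patients, %d events", n, int(event.sum()))
    return df


@dataclass
class SimulatedDataset:
    """One synthetic cohort: inputs for every pipeline stage + ground truth."""

    config: SimulationConfig
    chipdef: ChipDefinition
    intensities: pd.DataFrame
    clinical: pd.DataFrame
    sf_genes: list[str]
    ground_truth: GroundTruth

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "chipdef": out / "chipdef.tsv",
            "intensities": out / "intensities.tsv",
            "sf_list": out / "sf_list.txt",
            "clinical": out / "clinical.csv",
            "ground_truth": out / "ground_truth.json",
        }
        tio.write_chipdef(paths["chipdef"], self.chipdef)
        tio.write_matrix(paths["intensities"], self.intensities,
                         index_name="probe_id")
        tio.write_gene_list(paths["sf_list"], self.sf_genes)
        tio.write_clinical(paths["clinical"], self.clinical)
        self.ground_truth.write_json(paths["ground_truth"])
        return paths


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Generate a complete cohort from one seeded random stream."""
    config = config or SimulationConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    chipdef = generate_chipdef(config, rng)
    intensities, truth = generate_intensities(chipdef, config, rng)
    tin_flags = pd.Series(False, index=intensities.columns)
    tin_flags[truth.tin_samples] = True
    clinical = generate_clinical(tin_flags, config, rng)
    return SimulatedDataset(config=config, chipdef=chipdef,
                            intensities=intensities, clinical=clinical,
                            sf_genes=truth.sf_genes, ground_truth=truth)
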