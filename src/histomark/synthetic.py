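"""Synthetic cohort generator.

Emulates the statistical structure of a multi-centre lung-adenocarcinoma
cohort with paired histology and transcriptomics: per-sample continuous gene
expression, bags of patch feature vectors in which a subset of "informative"
patches carries the expression signal, overall-survival times driven by a
Cox model with age/sex/stage covariates and independent censoring,
unbalanced tissue-source-site labels, and small two-stain RGB tiles for the
preprocessing stage.

Every generator is a pure function of its configuration (including the
seed): calling it twice yields identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "CohortConfig",
    "PatchBag",
    "ExpressionMatrix",
    "SyntheticCohort",
    "generate_expression",
    "generate_bags",
    "generate_survival",
    "generate_tiles",
    "generate_cohort",
    "survival_design",
    "write_cohort",
    "write_tiles",
]

CLINICAL_COLUMNS = ["sample_id", "age", "sex", "stage", "os_months", "os_event", "site"]


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    The defaults define a small cohort that preserves the structure of the
    real problem (multi-site, censored survival, weak patch-level labels)
    at a size a single CPU handles comfortably: 200 samples, 32-d features,
    64 patches per bag.  All dimensions scale up to the real setting
    (768-d features, ~500 patches, ~460 samples) if asked.

    ``cox_coefficients`` holds the log-hazard effects of the (standardized)
    gene expression values followed by the age, sex and stage effects; its
    length must equal ``n_genes + 3``.
    """

    n_samples: int = 200
    n_genes: int = 3
    feature_dim: int = 32
    patches_per_bag: int = 64
    informative_fraction: float = 0.3
    noise_sd: float = 0.1
    n_sites: int = 12
    cox_coefficients: tuple = None  # type: ignore[assignment]
    baseline_hazard_scale: float = 60.0  # months
    baseline_hazard_shape: float = 1.2
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.cox_coefficients is None:
            # one harmful planted gene, remaining genes null; mild clinical effects
            coefs = [0.0] * self.n_genes + [0.2, 0.1, 0.3]
            coefs[0] = 1.0
            object.__setattr__(self, "cox_coefficients", tuple(coefs))
        else:
            object.__setattr__(self, "cox_coefficients", tuple(self.cox_coefficients))
        for name in ("n_samples", "n_genes", "feature_dim", "patches_per_bag", "n_sites"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if not 0.0 < self.informative_fraction <= 1.0:
            raise ConfigurationError("informative_fraction must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.n_sites < 5:
            raise ConfigurationError("n_sites must be at least 5 (one site per fold)")
        if self.n_sites > self.n_samples:
            raise ConfigurationError("n_sites cannot exceed n_samples")
        if round(self.informative_fraction * self.patches_per_bag) < 1:
            raise ConfigurationError(
                "informative_fraction * patches_per_bag must be at least 1"
            )
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must lie in [0, 1)")
        if len(self.cox_coefficients) != self.n_genes + 3:
            raise ConfigurationError(
                "cox_coefficients must have length n_genes + 3 "
                f"(got {len(self.cox_coefficients)}, expected {self.n_genes + 3})"
            )
        if self.baseline_hazard_scale <= 0 or self.baseline_hazard_shape <= 0:
            raise ConfigurationError("Weibull baseline scale/shape must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible substream per generator stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class PatchBag:
    """One sample's set of patch feature vectors — the MIL bag."""

    sample_id: str
    features: np.ndarray  # K x D
    site: str

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("bag features must be a non-empty K x D matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("bag features must be finite")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]


class ExpressionMatrix:
    """Genes x samples continuous expression, thin wrapper over a DataFrame."""

    def __init__(self, values, genes=None, samples=None):
        if isinstance(values, pd.DataFrame):
            self.df = values.astype(float)
        else:
            values = np.asarray(values, dtype=float)
            self.df = pd.DataFrame(values, index=genes, columns=samples)
        if self.df.shape[0] < 1 or self.df.shape[1] < 1:
            raise ConfigurationError("expression matrix must be non-empty")

    @property
    def genes(self):
        return list(self.df.index)

    @property
    def samples(self):
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def gene(self, name) -> pd.Series:
        return self.df.loc[name]

    def standardized(self) -> "ExpressionMatrix":
        """Per-gene z-scores across samples."""
        v = self.values
        sd = v.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        return ExpressionMatrix(
            (v - v.mean(axis=1, keepdims=True)) / sd, self.genes, self.samples
        )

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def __repr__(self):
        return f"ExpressionMatrix({self.df.shape[0]} genes x {self.df.shape[1]} samples)"


@dataclass
class SyntheticCohort:
    """A full synthetic cohort: bags, ground-truth expression, clinical table."""

    bags: list
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    signal_directions: np.ndarray  # n_genes x feature_dim, orthonormal rows
    informative_mask: list  # per bag, boolean K-vector
    config: CohortConfig

    def __post_init__(self):
        ids = [b.sample_id for b in self.bags]
        if ids != self.expression.samples or ids != list(self.clinical["sample_id"]):
            raise ValueError("bags, expression columns and clinical rows must align")


def _sample_ids(n: int):
    return [f"S{i:04d}" for i in range(n)]


def generate_expression(config: CohortConfig) -> ExpressionMatrix:
    """Draw per-gene Gaussian expression with gene-specific mean and sd.

    Gene means are drawn from N(10, 3) and gene standard deviations from
    U(0.5, 2), emulating processed (log-scale) expression magnitudes;
    downstream stages standardize per gene, so the absolute location is
    arbitrary.
    """
    rng = config.rng(1)
    means = rng.normal(10.0, 3.0, size=config.n_genes)
    sds = rng.uniform(0.5, 2.0, size=config.n_genes)
    vals = rng.normal(
        means[:, None], sds[:, None], size=(config.n_genes, config.n_samples)
    )
    genes = [f"G{i:03d}" for i in range(config.n_genes)]
    return ExpressionMatrix(vals, genes=genes, samples=_sample_ids(config.n_samples))


def gene_population_moments(config: CohortConfig):
    """The per-gene (mean, sd) pairs generate_expression draws from."""
    rng = config.rng(1)
    means = rng.normal(10.0, 3.0, size=config.n_genes)
    sds = rng.uniform(0.5, 2.0, size=config.n_genes)
    return means, sds


def _site_sizes(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Unequal site sizes via a flat Dirichlet, largest-remainder rounded."""
    w = rng.dirichlet(np.ones(config.n_sites))
    raw = w * (config.n_samples - config.n_sites)
    sizes = np.floor(raw).astype(int)
    rem = (config.n_samples - config.n_sites) - sizes.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    sizes[order[:rem]] += 1
    return sizes + 1  # every site has at least one sample


def generate_bags(expression: ExpressionMatrix, config: CohortConfig,
                  signal_directions: np.ndarray | None = None):
    """Build one patch bag per sample with planted expression signal.

    A fraction ``informative_fraction`` of the patches in each bag has its
    mean shifted along each gene's (orthonormal) signal direction by that
    sample's standardized expression; the remaining patches are pure
    N(0, noise_sd^2) noise.  Sites are contiguous blocks of samples with
    unequal sizes.

    Pass ``signal_directions`` from another cohort to emulate an external
    validation cohort: the gene-morphology link (the biology) is shared
    while samples, sites and noise are drawn fresh.

    Returns ``(bags, signal_directions, informative_mask)``.
    """
    n = config.n_samples
    if len(expression.samples) != n:
        raise ConfigurationError("expression columns must equal n_samples")
    if config.n_genes > config.feature_dim:
        raise ConfigurationError("feature_dim must be >= n_genes for orthonormal signals")
    rng = config.rng(2)

    q, _ = np.linalg.qr(rng.normal(size=(config.feature_dim, config.n_genes)))
    directions = q.T if signal_directions is None else np.asarray(signal_directions)
    if directions.shape != (config.n_genes, config.feature_dim):
        raise ConfigurationError("signal_directions shape mismatch")

    z = expression.standardized().values  # n_genes x n_samples
    k = config.patches_per_bag
    n_inf = int(round(config.informative_fraction * k))

    sizes = _site_sizes(config, rng)
    site_of = np.repeat([f"SITE{i:02d}" for i in range(config.n_sites)], sizes)

    bags, masks = [], []
    ids = expression.samples
    for j in range(n):
        feats = rng.normal(0.0, config.noise_sd, size=(k, config.feature_dim))
        mask = np.zeros(k, dtype=bool)
        idx = rng.choice(k, size=n_inf, replace=False)
        mask[idx] = True
        shift = z[:, j] @ directions  # D-vector
        feats[mask] += shift
        bags.append(PatchBag(ids[j], feats, site_of[j]))
        masks.append(mask)
    return bags, directions, masks


def generate_clinical_covariates(config: CohortConfig) -> pd.DataFrame:
    """Age ~ N(65, 10), sex ~ Bernoulli(0.5), stage ordinal 1-4 (50/25/15/10%)."""
    rng = config.rng(3)
    n = config.n_samples
    return pd.DataFrame(
        {
            "sample_id": _sample_ids(n),
            "age": np.round(rng.normal(65.0, 10.0, size=n), 1),
            "sex": rng.integers(0, 2, size=n),
            "stage": rng.choice([1, 2, 3, 4], size=n, p=[0.50, 0.25, 0.15, 0.10]),
        }
    )


def survival_design(expression: ExpressionMatrix, covariates: pd.DataFrame):
    """Design matrix the survival simulation uses: standardized gene values,
    then centred/scaled age ((age-65)/10), sex and stage-1.

    Shared by the generator and by parameter-recovery checks so the fitted
    coefficients are on the same scale as ``CohortConfig.cox_coefficients``.
    """
    z = expression.standardized().values.T  # samples x genes
    age = (covariates["age"].to_numpy() - 65.0) / 10.0
    sex = covariates["sex"].to_numpy().astype(float)
    stage = covariates["stage"].to_numpy().astype(float) - 1.0
    x = np.column_stack([z, age, sex, stage])
    names = list(expression.genes) + ["age", "sex", "stage"]
    return x, names


def generate_survival(
    expression: ExpressionMatrix,
    clinical_covariates: pd.DataFrame | None,
    config: CohortConfig,
) -> pd.DataFrame:
    """Simulate overall survival from a Weibull-baseline Cox model.

    Event times are drawn by inverse-transform sampling: with linear
    predictor eta = beta @ x, survival S(t) = exp(-(t/lambda)^k * e^eta), so
    T = lambda * (E / e^eta)^(1/k) with E ~ Exp(1).  Censoring times are
    exponential with the rate bisected (deterministically, on the same
    draws) so the realized censoring fraction matches ``censoring_rate``.
    """
    if clinical_covariates is None:
        clinical_covariates = generate_clinical_covariates(config)
    x, _ = survival_design(expression, clinical_covariates)
    beta = np.asarray(config.cox_coefficients, dtype=float)
    if x.shape[1] != beta.size:
        raise ConfigurationError(
            f"cox_coefficients length {beta.size} does not match design width {x.shape[1]}"
        )
    rng = config.rng(4)
    n = config.n_samples
    eta = x @ beta
    e = rng.exponential(1.0, size=n)
    t_event = config.baseline_hazard_scale * np.power(
        e / np.exp(eta), 1.0 / config.baseline_hazard_shape
    )

    if config.censoring_rate == 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        u = rng.uniform(size=n)

        def censored_frac(rate):
            c = -np.log(u) / rate
            return float(np.mean(c < t_event))

        lo, hi = 1e-8, 1e4
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if censored_frac(mid) < config.censoring_rate:
                lo = mid
            else:
                hi = mid
        rate = np.sqrt(lo * hi)
        c = -np.log(u) / rate
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)

    time = np.maximum(time, 1e-6)  # survival times strictly positive
    out = clinical_covariates.copy()
    out["os_months"] = time
    out["os_event"] = event
    return out


# ---------------------------------------------------------------------------
# Synthetic stained tiles

# Reference H&E optical-density stain vectors (unit norm): haematoxylin
# absorbs strongly in green/red, eosin mostly in green/blue.
HEMATOXYLIN_OD = np.array([0.56258278, 0.72007796, 0.40618757])
EOSIN_OD = np.array([0.21589894, 0.80119605, 0.55809725])


def _od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of OD = -log10((I+1)/256)."""
    img = 256.0 * np.power(10.0, -od) - 1.0
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_tiles(
    size: int = 224,
    seed: int = 0,
    od_noise_sd: float = 0.0,
    blur_sigma: float = 6.0,
) -> dict:
    """Emit labelled 224x224 RGB fixtures for the preprocessing stage.

    Returns a dict with keys ``background`` (uniform near-white),
    ``sharp`` (two-stain tissue: smooth random concentration fields mixed
    through the H&E stain vectors in optical density), ``blurred``
    (Gaussian-blurred copy of the sharp tile) and ``checkerboard``
    (2-pixel period), plus ``stain_matrix`` (3x2, the planted unit-norm
    stain vectors) and ``concentrations`` (size x size x 2 ground truth).
    """
    rng = np.random.default_rng([seed, 17])
    background = np.full((size, size, 3), 245, dtype=np.uint8)

    # haematoxylin in sharp nuclei-like blobs, eosin in broad smooth fields;
    # each field has regions where the other stain vanishes, so nearly pure
    # pixels of both stains exist
    f_h = gaussian_filter(rng.normal(size=(size, size)), sigma=3.0)
    c_h = np.clip(f_h - np.percentile(f_h, 60), 0, None)
    c_h *= 1.9 / max(c_h.max(), 1e-9)
    c_h = np.minimum(c_h, 1.3)  # dye saturation keeps nuclei off pure black
    f_e = gaussian_filter(rng.normal(size=(size, size)), sigma=10.0)
    c_e = np.clip(f_e, 0, None)
    c_e *= 1.0 / max(c_e.max(), 1e-9)

    stains = np.column_stack([HEMATOXYLIN_OD, EOSIN_OD])  # 3x2
    conc = np.stack([c_h, c_e], axis=-1)  # H x W x 2
    od = conc @ stains.T
    if od_noise_sd > 0:
        od = od + rng.normal(0.0, od_noise_sd, size=od.shape)
        od = np.clip(od, 0, None)
    sharp = _od_to_rgb(od)

    blurred = np.stack(
        [gaussian_filter(sharp[..., ch].astype(float), sigma=blur_sigma) for ch in range(3)],
        axis=-1,
    )
    blurred = np.clip(np.round(blurred), 0, 255).astype(np.uint8)

    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    board = ((rr // 4 + cc // 4) % 2 * 255).astype(np.uint8)
    checkerboard = np.stack([board] * 3, axis=-1)

    return {
        "background": background,
        "sharp": sharp,
        "blurred": blurred,
        "checkerboard": checkerboard,
        "stain_matrix": stains,
        "concentrations": conc,
    }


def generate_cohort(config: CohortConfig,
                    signal_directions: np.ndarray | None = None) -> SyntheticCohort:
    """End-to-end cohort: expression -> bags -> clinical covariates -> survival.

    With ``signal_directions`` from an existing cohort this draws an
    external-validation cohort with the same gene-morphology biology."""
    expression = generate_expression(config)
    bags, directions, masks = generate_bags(expression, config, signal_directions)
    covariates = generate_clinical_covariates(config)
    clinical = generate_survival(expression, covariates, config)
    clinical["site"] = [b.site for b in bags]
    return SyntheticCohort(bags, expression, clinical[CLINICAL_COLUMNS], directions, masks, config)


def write_tiles(tiles: dict, out_dir) -> list:
    """Save the labelled RGB tile fixtures as PNG files; returns the paths."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in tiles.items():
        if isinstance(arr, np.ndarray) and arr.ndim == 3 and arr.dtype == np.uint8:
            p = out / f"{name}.png"
            Image.fromarray(arr).save(p)
            paths.append(p)
    return paths


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write expression TSV (genes x samples), clinical TSV, one .npy per bag
    plus a JSON manifest — the on-disk layout downstream stages read."""
    out = Path(out_dir)
    (out / "bags").mkdir(parents=True, exist_ok=True)
    cohort.expression.to_tsv(out / "expression.tsv")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    manifest = []
    for bag in cohort.bags:
        fn = f"bags/{bag.sample_id}.npy"
        np.save(out / fn, bag.features)
        manifest.append(
            {"sample_id": bag.sample_id, "site": bag.site, "file": fn,
             "n_patches": int(bag.n_patches)}
        )
    (out / "bags_manifest.json").write_text(json.dumps(manifest, indent=1))
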