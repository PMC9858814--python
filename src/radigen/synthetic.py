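"""Synthetic radiogenomic cohorts with known ground truth.

Generates everything the pipeline consumes — tumor phantoms, four-timepoint
DCE series, negative-binomial RNA-seq counts and hallmark-style gene sets —
from latent per-patient phenotypes (size, wash-in, wash-out, heterogeneity),
so that every downstream stage can be tested against planted associations.

The kinetic model is a mono-exponential wash-in multiplied by an exponential
wash-out,

    I(t) = I_pre * (1 + A * (1 - exp(-k t)) * exp(-w t)),

chosen for closed-form verifiability rather than pharmacokinetic realism.
Latent-to-imaging and latent-to-pathway links share a Gaussian copula: a
planted correlation rho between a latent and a pathway activity is exact in
latent space; its attenuation through imaging and expression noise is
measured by the tests, not assumed.

Expression counts are negative binomial with log-mean
``baseline_g + effect_size * activity_{s(g)}`` for member genes of set s(g),
scaled by per-sample library size; non-member genes are independent of all
activities.  Gene sets are disjoint by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, special

from radigen._utils import derive_seed
from radigen.dce_maps import DceSeries

LATENT_NAMES = ("size", "washin", "washout", "heterogeneity")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, kinetics and noise of the imaging phantom cohort."""

    n_patients: int = 20
    grid_shape: tuple[int, int, int] = (64, 64, 64)  # (z, y, x) voxels
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range: tuple[float, float] = (8.0, 16.0)  # mm
    lobulation: float = 1.0  # surface-perturbation amplitude, >= 0
    washin_rate_range: tuple[float, float] = (1.0, 4.0)  # per minute
    washout_range: tuple[float, float] = (0.02, 0.30)  # per minute
    texture_heterogeneity_range: tuple[float, float] = (0.1, 0.6)
    enhancement_amplitude: float = 1.5  # peak relative enhancement A
    baseline_intensity: float = 100.0
    noise_sd: float = 0.02  # relative intensity noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(g < 16 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 16")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        extent = min(g * s for g, s in zip(self.grid_shape, self.spacing_mm))
        if self.tumor_radius_range[1] * 2 >= extent:
            raise ValueError("tumor_radius_range max too large for the grid")
        for name in (
            "tumor_radius_range",
            "washin_rate_range",
            "washout_range",
            "texture_heterogeneity_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy min <= max")
        if self.lobulation < 0 or self.noise_sd < 0:
            raise ValueError("lobulation and noise_sd must be >= 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")


@dataclass(frozen=True)
class ExpressionConfig:
    """Negative-binomial count-matrix generator settings."""

    n_genes: int = 2000
    n_sets: int = 10
    set_size_range: tuple[int, int] = (20, 40)
    nb_dispersion: float = 0.2  # var = mu + dispersion * mu^2
    baseline_log_mean_range: tuple[float, float] = (2.0, 6.0)  # natural log
    library_size_range: tuple[float, float] = (0.7, 1.3)
    effect_size: float = 1.0  # log-mean shift per unit activity (member genes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_sets * self.set_size_range[1] > self.n_genes:
            raise ValueError("gene sets (drawn disjoint) exceed the gene universe")
        for name in ("set_size_range", "baseline_log_mean_range", "library_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy min <= max")
        if self.library_size_range[0] <= 0:
            raise ValueError("library sizes must be positive")


@dataclass
class SyntheticTruth:
    """Ground-truth record of a planted cohort."""

    latent_phenotypes: pd.DataFrame  # patients x latents (standard normal)
    pathway_activity: pd.DataFrame  # patients x sets (standard normal)
    planted_pairs: list[tuple[str, str, float]]  # (latent, set, rho)
    kinetic_params: pd.DataFrame | None = None  # patients x (washin, washout, ...)

    def as_dict(self) -> dict:
        return {
            "latent_phenotypes": self.latent_phenotypes.round(10).to_dict("index"),
            "pathway_activity": self.pathway_activity.round(10).to_dict("index"),
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "kinetic_params": (
                self.kinetic_params.round(10).to_dict("index")
                if self.kinetic_params is not None
                else None
            ),
        }


def _range_map(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map standard-normal latents into [lo, hi] via the probability integral."""
    return lo + special.ndtr(z) * (hi - lo)


def _smooth_field(shape, rng, sigma_vox: float = 4.0) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def make_tumor_mask(
    config: PhantomConfig,
    patient_index: int,
    semi_axes_mm: tuple[float, float, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Lobulated ellipsoid phantom mask for one patient.

    The base shape is an ellipsoid with semi-axes drawn from
    ``tumor_radius_range``; its surface is perturbed by a smooth random field
    whose amplitude is 5% of the radius per unit ``lobulation``.  The result
    is the largest 6-connected component, hole-filled.

    Returns the boolean mask and a descriptor dict (true semi-axes in mm and
    foreground voxel count).
    """
    if patient_index >= config.n_patients:
        raise ValueError(f"patient_index {patient_index} >= n_patients")
    rng = np.random.default_rng(derive_seed(config.seed, f"mask:{patient_index}"))
    lo, hi = config.tumor_radius_range
    if semi_axes_mm is None:
        semi_axes_mm = tuple(rng.uniform(lo, hi, size=3))
    axes = np.asarray(semi_axes_mm, dtype=float)

    shape = np.asarray(config.grid_shape)
    spacing = np.asarray(config.spacing_mm)
    center = (shape - 1) * spacing / 2.0
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    radial = np.sqrt(
        ((zz - center[0]) / axes[0]) ** 2
        + ((yy - center[1]) / axes[1]) ** 2
        + ((xx - center[2]) / axes[2]) ** 2
    )
    threshold = 1.0
    if config.lobulation > 0:
        bump = _smooth_field(tuple(shape), rng)
        threshold = 1.0 + 0.05 * config.lobulation * bump
    mask = radial <= threshold

    labels, n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n_comp == 0:
        raise ValueError(f"patient {patient_index}: drawn tumor produced an empty mask")
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)

    border = (
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    if border:
        raise ValueError(
            f"patient {patient_index}: grid too small to contain the drawn tumor"
        )
    return mask, {
        "semi_axes_mm": tuple(float(a) for a in axes),
        "voxel_count": int(mask.sum()),
    }


@dataclass(frozen=True)
class KineticParams:
    """Per-patient enhancement-curve parameters."""

    washin: float  # k, per minute
    washout: float  # w, per minute
    heterogeneity: float  # amplitude-field relative SD
    amplitude: float = 1.5  # A, peak relative enhancement


def enhancement_curve(t, amplitude, washin, washout):
    """Closed-form relative enhancement (1 - e^{-k t}) e^{-w t} scaled by A."""
    t = np.asarray(t, dtype=float)
    return amplitude * (1.0 - np.exp(-washin * t)) * np.exp(-washout * t)


def simulate_dce(
    mask: np.ndarray,
    kinetics: KineticParams,
    config: PhantomConfig,
    patient_index: int = 0,
) -> DceSeries:
    """Four-timepoint DCE series (t = 0, 1, 3, 5 min) for one phantom.

    Tumor voxels follow ``I_pre * (1 + A_v * (1 - e^{-k t}) * e^{-w t})``
    where the voxel amplitude A_v modulates the patient amplitude by a smooth
    spatial field with relative SD ``heterogeneity``; background voxels stay
    at baseline.  Relative Gaussian noise of SD ``noise_sd`` is added to
    every volume and intensities are clipped positive.
    """
    for name, v in (("washin", kinetics.washin), ("washout", kinetics.washout),
                    ("heterogeneity", kinetics.heterogeneity),
                    ("amplitude", kinetics.amplitude)):
        if not np.isfinite(v):
            raise ValueError(f"kinetic parameter {name} must be finite")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if config.baseline_intensity <= 0:
        raise ValueError("non-positive pre-contrast baseline")
    rng = np.random.default_rng(derive_seed(config.seed, f"dce:{patient_index}"))

    base = np.full(mask.shape, config.baseline_intensity, dtype=float)
    amp = np.zeros(mask.shape)
    if kinetics.heterogeneity > 0:
        fld = _smooth_field(mask.shape, rng)
        amp[mask] = kinetics.amplitude * np.clip(
            1.0 + kinetics.heterogeneity * fld[mask], 0.05, None
        )
    else:
        amp[mask] = kinetics.amplitude

    times = {"pre": 0.0, "early": 1.0, "middle": 3.0, "late": 5.0}
    volumes = {}
    for label, t in times.items():
        kinetic = (1.0 - np.exp(-kinetics.washin * t)) * np.exp(-kinetics.washout * t)
        vol = base * (1.0 + amp * kinetic)
        if config.noise_sd > 0:
            vol = vol * (1.0 + config.noise_sd * rng.standard_normal(mask.shape))
        volumes[label] = np.clip(vol, 1e-6, None)
    return DceSeries(
        volumes=volumes,
        spacing_mm=tuple(config.spacing_mm),
        patient_id=f"P{patient_index:03d}",
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _make_gene_sets(config: ExpressionConfig, rng) -> dict[str, list[str]]:
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    sizes = rng.integers(
        config.set_size_range[0], config.set_size_range[1] + 1, size=config.n_sets
    )
    pool = rng.permutation(config.n_genes)
    sets, start = {}, 0
    for i, size in enumerate(sizes):
        members = pool[start : start + int(size)]
        sets[f"SET{i:02d}"] = sorted(genes[g] for g in members)
        start += int(size)
    return sets


def simulate_expression(
    truth: SyntheticTruth,
    config: ExpressionConfig,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Negative-binomial count matrix whose member genes track pathway activity.

    Member genes of set s get log-mean ``baseline_g + effect_size * a_js``;
    all genes are scaled by a per-sample library size and drawn from a
    gamma-Poisson mixture with Var = mu + dispersion * mu^2.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "expression"))
    samples = list(truth.pathway_activity.index)
    n = len(samples)
    sets = _make_gene_sets(config, rng)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    membership = np.full(config.n_genes, -1)
    set_names = list(sets.keys())
    gene_idx = {g: i for i, g in enumerate(genes)}
    for si, name in enumerate(set_names):
        for g in sets[name]:
            membership[gene_idx[g]] = si

    baseline = rng.uniform(*config.baseline_log_mean_range, size=config.n_genes)
    lib = rng.uniform(*config.library_size_range, size=n)
    activity = truth.pathway_activity[set_names].to_numpy()  # n x n_sets

    log_mu = np.tile(baseline[:, None], (1, n))
    member_rows = membership >= 0
    log_mu[member_rows] += config.effect_size * activity[:, membership[member_rows]].T
    mu = np.exp(log_mu) * lib[None, :]

    r = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    return counts_df, sets


# ---------------------------------------------------------------------------
# cohort planting
# ---------------------------------------------------------------------------

def _draw_latents(n_patients: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(derive_seed(seed, "latents"))
    z = rng.standard_normal((n_patients, len(LATENT_NAMES)))
    ids = [f"P{i:03d}" for i in range(n_patients)]
    return pd.DataFrame(z, index=ids, columns=list(LATENT_NAMES))


def _plant_activities(
    latents: pd.DataFrame,
    set_names: list[str],
    planted_pairs: list[tuple[str, str, float]],
    seed: int,
) -> pd.DataFrame:
    """Pathway activities with exact planted latent correlations (copula).

    Planted sets get ``rho * z_latent + sqrt(1 - rho^2) * noise``; unplanted
    sets are independent standard normals.
    """
    for latent, set_name, rho in planted_pairs:
        if latent not in latents.columns:
            raise ValueError(f"unknown latent '{latent}' in planted pair")
        if set_name not in set_names:
            raise ValueError(f"unknown gene set '{set_name}' in planted pair")
        if abs(rho) > 1:
            raise ValueError(f"|rho| must be <= 1, got {rho}")
    rng = np.random.default_rng(derive_seed(seed, "activities"))
    n = len(latents)
    planted = {s: (l, r) for l, s, r in planted_pairs}
    cols = {}
    for name in set_names:
        eps = rng.standard_normal(n)
        if name in planted:
            latent, rho = planted[name]
            cols[name] = rho * latents[latent].to_numpy() + np.sqrt(1 - rho**2) * eps
        else:
            cols[name] = eps
    return pd.DataFrame(cols, index=latents.index)


def plant_cohort(
    phantom_cfg: PhantomConfig,
    expr_cfg: ExpressionConfig,
    planted_pairs: list[tuple[str, str, float]] | None = None,
) -> tuple[list[DceSeries], list[np.ndarray], pd.DataFrame, dict, SyntheticTruth]:
    """Full synthetic cohort: DCE series, masks, counts, gene sets, truth.

    The same latent phenotypes drive the imaging kinetics (via probability-
    integral mapping into the configured parameter ranges) and the pathway
    activities (via the Gaussian copula of :func:`_plant_activities`), so the
    planted latent–pathway correlation is exact in latent space.
    """
    planted_pairs = planted_pairs or []
    latents = _draw_latents(phantom_cfg.n_patients, phantom_cfg.seed)
    set_names = [f"SET{i:02d}" for i in range(expr_cfg.n_sets)]
    activity = _plant_activities(latents, set_names, planted_pairs, expr_cfg.seed)

    kin_rows = []
    series_list, masks = [], []
    lo_r, hi_r = phantom_cfg.tumor_radius_range
    for i, pid in enumerate(latents.index):
        rng = np.random.default_rng(derive_seed(phantom_cfg.seed, f"geom:{i}"))
        base_r = _range_map(latents.loc[pid, "size"], lo_r, hi_r)
        semi_axes = tuple(base_r * rng.uniform(0.8, 1.2, size=3))
        mask, _ = make_tumor_mask(phantom_cfg, i, semi_axes_mm=semi_axes)
        kin = KineticParams(
            washin=float(_range_map(latents.loc[pid, "washin"], *phantom_cfg.washin_rate_range)),
            washout=float(_range_map(latents.loc[pid, "washout"], *phantom_cfg.washout_range)),
            heterogeneity=float(
                _range_map(
                    latents.loc[pid, "heterogeneity"],
                    *phantom_cfg.texture_heterogeneity_range,
                )
            ),
            amplitude=phantom_cfg.enhancement_amplitude,
        )
        series_list.append(simulate_dce(mask, kin, phantom_cfg, patient_index=i))
        masks.append(mask)
        kin_rows.append(
            {"washin": kin.washin, "washout": kin.washout,
             "heterogeneity": kin.heterogeneity, "amplitude": kin.amplitude}
        )

    truth = SyntheticTruth(
        latent_phenotypes=latents,
        pathway_activity=activity,
        planted_pairs=list(planted_pairs),
        kinetic_params=pd.DataFrame(kin_rows, index=latents.index),
    )
    counts, sets = simulate_expression(truth, expr_cfg)
    return series_list, masks, counts, sets, truth


def simulate_association_cohort(
    n_patients: int = 150,
    n_features: int = 20,
    expr_cfg: ExpressionConfig | None = None,
    planted_pairs: list[tuple[str, str, float]] | None = None,
    feature_noise_sd: float = 0.35,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, SyntheticTruth]:
    """Feature-level synthetic cohort for association-stage studies.

    Skips phantom rendering: each "radiomic feature" is its own latent
    phenotype observed with Gaussian noise (``feature_noise_sd`` relative to
    the unit latent SD), and pathway activities are planted against those
    latents exactly as in :func:`plant_cohort`.  Planted pairs reference
    latents by feature name (``feat00`` ...).

    Returns (features patients x n_features, counts genes x patients,
    gene sets, truth).
    """
    expr_cfg = expr_cfg or ExpressionConfig(seed=derive_seed(seed, "expr"))
    planted_pairs = planted_pairs or []
    rng = np.random.default_rng(derive_seed(seed, "assoc-cohort"))
    ids = [f"P{i:03d}" for i in range(n_patients)]
    feat_names = [f"feat{i:02d}" for i in range(n_features)]
    z = rng.standard_normal((n_patients, n_features))
    latents = pd.DataFrame(z, index=ids, columns=feat_names)
    features = latents + feature_noise_sd * rng.standard_normal(latents.shape)

    set_names = [f"SET{i:02d}" for i in range(expr_cfg.n_sets)]
    activity = _plant_activities(latents, set_names, planted_pairs, expr_cfg.seed)
    truth = SyntheticTruth(
        latent_phenotypes=latents,
        pathway_activity=activity,
        planted_pairs=list(planted_pairs),
    )
    counts, sets = simulate_expression(truth, expr_cfg)
    return features, counts, sets, truth


def cohort_manifest(
    phantom_cfg: PhantomConfig,
    expr_cfg: ExpressionConfig,
    truth: SyntheticTruth,
    paths: dict[str, str],
) -> str:
    """Deterministic JSON manifest of a planted cohort (no timestamps)."""
    record = {
        "phantom_config": asdict(phantom_cfg),
        "expression_config": asdict(expr_cfg),
        "paths": dict(sorted(paths.items())),
        "truth": truth.as_dict(),
        "provenance": {
            "bias_field_correction": "assumed done upstream (inputs treated as corrected)"
        },
    }
    return json.dumps(record, indent=2, sort_keys=True)
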