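"""Synthetic cohorts, slides, and mutation tables with planted ground truth.

The generators emulate the statistical structure the downstream pipelines
assume, not real glioblastoma biology:

* ``simulate_cohort`` — a bulk expression cohort whose hazard depends
  log-linearly on the activity of a small set of planted, co-expressed
  ligand-receptor pairs, with independent exponential censoring.
* ``simulate_slide`` — an H&E-like image composed of 256x256 tiles drawn
  from k morphological classes, rendered by Beer-Lambert mixing of two
  stain vectors, whose tumor-class proportion determines a binary risk
  label.
* ``simulate_mutations`` — Bernoulli mutation calls with group-dependent
  per-gene frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

PATCH = 256

# Canonical H&E stain optical-density vectors (columns = hematoxylin, eosin),
# unit-normalized. Overridable wherever a stain matrix is accepted.
HE_STAIN_MATRIX = np.array(
    [[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]]
)
HE_STAIN_MATRIX = HE_STAIN_MATRIX / np.linalg.norm(HE_STAIN_MATRIX, axis=0)

# Per-class mean stain concentrations (hematoxylin, eosin) for up to 8
# morphological classes; spread out so classes are visually distinct.
DEFAULT_CLASS_PROFILES = np.array(
    [
        [1.00, 0.20],
        [0.20, 1.00],
        [0.65, 0.65],
        [1.60, 0.50],
        [0.50, 1.60],
        [1.40, 1.40],
        [0.30, 0.30],
        [1.80, 0.90],
    ]
)


@dataclass
class CohortTruth:
    """Planted ground truth for a simulated survival cohort."""

    planted_pairs: list
    betas: list
    latent_rho: float = 0.7
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if len(self.betas) != len(self.planted_pairs):
            raise ValueError("betas and planted_pairs must have equal length")
        if not 0.0 <= self.latent_rho <= 1.0:
            raise ValueError("latent_rho must lie in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass
class SlideTruth:
    """Planted ground truth for a simulated slide."""

    class_of_patch: np.ndarray | None = None  # grid of class ids, -1 = background
    slide_label: int | None = None
    class_stain_profiles: np.ndarray | None = None  # k x 2 mean concentrations
    tumor_classes: frozenset = frozenset({0, 1})
    label_threshold: float = 0.35
    seed: int = 0


def pair_id(ligand: str, receptor: str) -> str:
    return f"{ligand}_{receptor}"


def make_catalog(catalog_size: int, n_pathways: int = 12) -> pd.DataFrame:
    """Deterministic L-R catalog: pair j links LIG{j} to REC{j}."""
    rows = []
    for j in range(catalog_size):
        lig, rec = f"LIG{j:04d}", f"REC{j:04d}"
        rows.append((lig, rec, f"PW{j % n_pathways:02d}"))
    df = pd.DataFrame(rows, columns=["ligand", "receptor", "pathway"])
    df.index = [pair_id(l, r) for l, r in zip(df.ligand, df.receptor)]
    df.index.name = "pair"
    return df


def default_planted_pairs(n: int) -> list:
    """Ids of the first n catalog pairs, for constructing a CohortTruth."""
    return [pair_id(f"LIG{j:04d}", f"REC{j:04d}") for j in range(n)]


def _nb_draw(rng, mu, dispersion):
    """Negative binomial with mean mu and var mu + dispersion*mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_cohort(
    n_samples: int,
    n_genes: int,
    catalog_size: int,
    truth: CohortTruth,
    dispersion: float = 0.3,
    baseline_hazard: float = math.log(2) / 400.0,
    mean_log_expr: float = 4.0,
    sd_log_expr: float = 1.0,
):
    """Simulate expression, survival, and an L-R catalog with planted pairs.

    Counts are negative-binomial around log-normal per-gene means. Each
    planted pair's ligand and receptor share a per-sample Gaussian latent
    factor on the log scale, scaled so their across-sample rank correlation
    targets ``truth.latent_rho``. The hazard of sample i is
    ``h0 * exp(sum_j beta_j * s_ij)`` where ``s_ij`` is the standardized
    activity (geometric mean of log1p ligand/receptor expression) of
    planted pair j. Event times are exponential given the hazard; censoring
    times are independent exponentials tuned so the expected censored
    fraction equals ``truth.censor_rate``. Age and gender are generated
    independently of risk.

    Returns ``(expression genes x samples, survival table, catalog, truth)``.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    if n_genes < 2 * catalog_size:
        raise ValueError("n_genes must be >= 2 * catalog_size")
    catalog = make_catalog(catalog_size)
    missing = [p for p in truth.planted_pairs if p not in catalog.index]
    if missing:
        raise ValueError(f"planted pair not in catalog: {missing[0]}")

    rng = np.random.default_rng(truth.seed)
    gene_ids = list(catalog.ligand) + list(catalog.receptor) + [
        f"BG{j:05d}" for j in range(n_genes - 2 * catalog_size)
    ]
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]

    log_mu = rng.normal(mean_log_expr, sd_log_expr, size=n_genes)
    # planted genes kept reasonably expressed so the latent factor is visible
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    planted_gene_idx = []
    for p in truth.planted_pairs:
        lig, rec = catalog.loc[p, "ligand"], catalog.loc[p, "receptor"]
        planted_gene_idx.append((gene_pos[lig], gene_pos[rec]))
    for il, ir in planted_gene_idx:
        log_mu[il] = max(log_mu[il], mean_log_expr)
        log_mu[ir] = max(log_mu[ir], mean_log_expr)

    log_mu_mat = np.tile(log_mu[:, None], (1, n_samples))
    rho = truth.latent_rho
    for (il, ir), _ in zip(planted_gene_idx, truth.planted_pairs):
        z = rng.standard_normal(n_samples)
        if rho > 0:
            # latent scale chosen so log-count correlation ~ rho, given
            # NB sampling noise var(log count) ~ log1p(dispersion + 1/mu)
            v_l = math.log1p(dispersion + math.exp(-log_mu[il]))
            v_r = math.log1p(dispersion + math.exp(-log_mu[ir]))
            v = 0.5 * (v_l + v_r)
            a = math.sqrt(rho * v / (1.0 - rho)) if rho < 1 else 10.0
            log_mu_mat[il] += a * z
            log_mu_mat[ir] += a * z

    counts = _nb_draw(rng, np.exp(log_mu_mat), dispersion)
    expr = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    expr.attrs["normalized"] = False

    # hazard from standardized planted-pair activities
    eta = np.zeros(n_samples)
    for (il, ir), beta in zip(planted_gene_idx, truth.betas):
        act = np.sqrt(np.log1p(counts[il]) * np.log1p(counts[ir]))
        sd = act.std()
        s = (act - act.mean()) / sd if sd > 0 else np.zeros(n_samples)
        eta += beta * s
    hazard = baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / hazard)

    if truth.censor_rate > 0:
        # P(censored_i) = c / (c + h_i); tune c so the mean equals the target
        def mean_censored(c):
            return float(np.mean(c / (c + hazard))) - truth.censor_rate

        c_rate = brentq(mean_censored, 1e-12, 1e6)
        t_cens = rng.exponential(1.0 / c_rate, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)

    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    surv = pd.DataFrame(
        {
            "OS.time": np.maximum(os_time, 1e-3),
            "OS": os_event,
            "age": np.clip(rng.normal(60, 12, n_samples).round(1), 18, 90),
            "gender": rng.choice(["female", "male"], n_samples),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return expr, surv, catalog, truth


def _nnls2(stain_matrix: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Vectorized non-negative least squares for a 3x2 stain basis.

    For two stains the NNLS solution is either the unconstrained solution
    (if non-negative) or the non-negative projection onto one stain axis.
    """
    s1, s2 = stain_matrix[:, 0], stain_matrix[:, 1]
    g = stain_matrix.T @ stain_matrix
    b = od @ stain_matrix  # N x 2
    det = g[0, 0] * g[1, 1] - g[0, 1] * g[1, 0]
    c1 = (g[1, 1] * b[:, 0] - g[0, 1] * b[:, 1]) / det
    c2 = (g[0, 0] * b[:, 1] - g[1, 0] * b[:, 0]) / det
    conc = np.stack([c1, c2], axis=1)
    neg = conc.min(axis=1) < 0
    if np.any(neg):
        a1 = np.clip(od[neg] @ s1 / (s1 @ s1), 0, None)
        a2 = np.clip(od[neg] @ s2 / (s2 @ s2), 0, None)
        r1 = np.linalg.norm(od[neg] - np.outer(a1, s1), axis=1)
        r2 = np.linalg.norm(od[neg] - np.outer(a2, s2), axis=1)
        pick1 = r1 <= r2
        fixed = np.zeros((neg.sum(), 2))
        fixed[pick1, 0] = a1[pick1]
        fixed[~pick1, 1] = a2[~pick1]
        conc[neg] = fixed
    return conc


_MESH_Y, _MESH_X = np.mgrid[0:PATCH, 0:PATCH]


def _render_patch(rng, conc_mean, stain_matrix, texture_noise, io=255.0):
    """Render one 256x256 tile by Beer-Lambert mixing of two stains."""
    conc = np.tile(np.asarray(conc_mean, dtype=float), (PATCH, PATCH, 1))
    if texture_noise > 0:
        n_blobs = rng.poisson(6)
        yy, xx = _MESH_Y, _MESH_X
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, PATCH, 2)
            sigma = rng.uniform(8, 24)
            amp = rng.uniform(0.15, 0.45) * texture_noise
            bump = amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
            stain = rng.integers(0, 2)
            conc[:, :, stain] += bump
        conc += rng.normal(0, 0.03 * texture_noise, size=conc.shape)
        conc = np.clip(conc, 0, None)
    od = conc @ stain_matrix.T
    img = io * np.power(10.0, -od) - 1.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def simulate_slide(
    k_classes: int,
    grid: tuple,
    background_frac: float,
    truth: SlideTruth,
    tumor_frac: float = 0.5,
    texture_noise: float = 1.0,
    label: int | None = None,
    label_shift: float = 0.0,
    noise_class_jitter: float = 0.0,
    stain_matrix: np.ndarray | None = None,
):
    """Render a synthetic slide of stain-mixed, textured 256x256 tiles.

    Each non-background grid cell is assigned one of ``k_classes``
    morphological classes and rendered by Beer-Lambert mixing of two stain
    vectors with class-specific mean concentrations plus blob texture.
    Background cells are near-white. The slide label is 1 iff the
    proportion of tumor-class patches among tissue patches exceeds
    ``truth.label_threshold``, unless an explicit ``label`` is supplied
    (in which case tumor-class concentrations are shifted by
    ``label * label_shift``, emulating label-dependent morphology).
    ``noise_class_jitter`` adds one shared random concentration offset per
    slide to all non-tumor classes, emulating slide-level staining
    variation that carries no label information.

    Returns ``(uint8 RGB image, filled SlideTruth)``.
    """
    rows, cols = grid
    if k_classes < 2:
        raise ValueError("k_classes must be >= 2")
    if rows < 2 or cols < 2:
        raise ValueError("grid dims must be >= 2")
    n_cells = rows * cols
    n_bg = int(round(n_cells * background_frac))
    if background_frac > 0 and n_bg == 0:
        raise ValueError("grid too small to honor background_frac")

    rng = np.random.default_rng(truth.seed)
    S = HE_STAIN_MATRIX if stain_matrix is None else np.asarray(stain_matrix)
    profiles = (
        DEFAULT_CLASS_PROFILES[:k_classes]
        if truth.class_stain_profiles is None
        else np.asarray(truth.class_stain_profiles)
    )
    tumor = sorted(c for c in truth.tumor_classes if c < k_classes)

    if truth.class_of_patch is None:
        cells = np.full(n_cells, -1, dtype=int)
        tissue_idx = rng.permutation(n_cells)[n_bg:]
        n_tissue = tissue_idx.size
        n_tumor = int(round(n_tissue * tumor_frac)) if tumor else 0
        non_tumor = [c for c in range(k_classes) if c not in tumor]
        tumor_cells = rng.choice(tumor, n_tumor) if n_tumor else np.array([], int)
        rest = (
            rng.choice(non_tumor, n_tissue - n_tumor)
            if non_tumor
            else rng.choice(tumor, n_tissue - n_tumor)
        )
        cells[tissue_idx] = np.concatenate([tumor_cells, rest])
        class_grid = cells.reshape(rows, cols)
    else:
        class_grid = np.asarray(truth.class_of_patch)
        if class_grid.shape != (rows, cols):
            raise ValueError("class_of_patch shape must match grid")

    tissue_mask = class_grid >= 0
    n_tissue = int(tissue_mask.sum())
    tumor_prop = (
        float(np.isin(class_grid, tumor)[tissue_mask].mean()) if n_tissue else 0.0
    )
    slide_label = int(tumor_prop > truth.label_threshold) if label is None else int(label)

    jitter = (
        rng.normal(0.0, noise_class_jitter, size=2)
        if noise_class_jitter > 0
        else np.zeros(2)
    )
    img = np.full((rows * PATCH, cols * PATCH, 3), 255, dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            cls = class_grid[r, c]
            if cls < 0:
                continue
            conc = profiles[cls].copy()
            if label is not None and slide_label == 1 and cls in tumor:
                conc = conc + label_shift
            if cls not in tumor:
                conc = np.clip(conc + jitter, 0.05, None)
            img[r * PATCH : (r + 1) * PATCH, c * PATCH : (c + 1) * PATCH] = (
                _render_patch(rng, conc, S, texture_noise)
            )

    out = SlideTruth(
        class_of_patch=class_grid,
        slide_label=slide_label,
        class_stain_profiles=profiles,
        tumor_classes=frozenset(tumor),
        label_threshold=truth.label_threshold,
        seed=truth.seed,
    )
    return img, out


def recover_classes_by_stain(image: np.ndarray, truth: SlideTruth,
                             stain_matrix: np.ndarray | None = None) -> np.ndarray:
    """Assign each tile to its nearest class stain profile (oracle decoder).

    With texture noise 0 this recovers ``truth.class_of_patch`` exactly.
    """
    S = HE_STAIN_MATRIX if stain_matrix is None else np.asarray(stain_matrix)
    rows, cols = truth.class_of_patch.shape
    out = np.full((rows, cols), -1, dtype=int)
    for r in range(rows):
        for c in range(cols):
            tile = image[r * PATCH : (r + 1) * PATCH, c * PATCH : (c + 1) * PATCH]
            if tile.mean() >= 250:
                continue
            od = -np.log10((tile.reshape(-1, 3).astype(float) + 1) / 255.0)
            conc = _nnls2(S, od).mean(axis=0)
            d = np.linalg.norm(truth.class_stain_profiles - conc, axis=1)
            out[r, c] = int(np.argmin(d))
    return out


def simulate_mutations(
    samples,
    genes,
    freq_by_group: dict,
    groups,
    seed: int = 0,
    variant_class: str = "Missense_Mutation",
) -> pd.DataFrame:
    """Bernoulli mutation calls with group-dependent per-gene frequencies.

    ``freq_by_group`` maps gene -> {group label: mutation probability};
    ``groups`` maps sample -> group label. Returns a long-format table
    (sample, gene, variant_class).
    """
    groups = pd.Series(groups, index=samples) if not isinstance(groups, pd.Series) else groups
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        freqs = freq_by_group[gene]
        for s in samples:
            g = groups.loc[s]
            if g not in freqs:
                raise ValueError(f"unknown group label: {g!r}")
            p = freqs[g]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1] for gene {gene}")
            if rng.random() < p:
                rows.append((s, gene, variant_class))
    return pd.DataFrame(rows, columns=["sample", "gene", "variant_class"])
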