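"""Presence-background habitat-suitability modelling.

Pipeline: buffer the occurrences to a training region, draw pseudo-absences
by geographic exclusion (G.E.) or environmental dissimilarity (E.S.),
partition data by spatial blocks or at random, fit a penalized
presence-background logistic model, and score it with AUC and TSS.

The model is an L1-penalized logistic regression of presence (1) versus
pseudo-absence (0) on standardized linear, quadratic and pairwise-product
features — the feature set under which a penalized logistic model is
equivalent to the logistic output of the MaxEnt family (maxnet). Bit-exact
replication of any particular MaxEnt release is out of scope; what matters
here is parameter recovery on virtual species and the block-versus-random
transferability contrast.

The presence "envelope" behind E.S. sampling is a robust Mahalanobis
ellipsoid (minimum covariance determinant location/scatter, chi-squared
cutoff); an optional one-class SVM backend sits behind the same contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import curve_fit

from .geo import EnvGridStack, cross_distance_km

log = logging.getLogger(__name__)

TSS_THRESHOLDS = np.round(np.linspace(0.0, 1.0, 101), 2)


# ---------------------------------------------------------------------------
# training region
# ---------------------------------------------------------------------------

@dataclass
class TrainingRegion:
    """Boolean in/out mask over the env grid: cells within ``buffer_km`` of
    any occurrence, intersected with valid-data cells."""

    mask: np.ndarray
    buffer_km: float


def _distance_to_occurrences_km(occ: pd.DataFrame, env: EnvGridStack) -> np.ndarray:
    """Per-cell distance (km) from cell centre to the nearest occurrence."""
    if env.is_geographic:
        gx, gy = env.center_grids()
        d = cross_distance_km(gx.ravel(), gy.ravel(),
                              occ["lon"].to_numpy(), occ["lat"].to_numpy(),
                              geographic=True)
        return d.min(axis=1).reshape(env.shape)
    # planar: exact Euclidean distance transform from occurrence cells
    row, col = env.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    inside = env.contains(row, col)
    seed = np.ones(env.shape, bool)
    seed[row[inside], col[inside]] = False
    d_cells = ndimage.distance_transform_edt(
        seed, sampling=(env.transform.dy, env.transform.dx))
    return d_cells


def build_training_region(occ: pd.DataFrame, env: EnvGridStack,
                          buffer_km: float = 200.0) -> TrainingRegion:
    """Cells within ``buffer_km`` of any occurrence, restricted to valid data."""
    if len(occ) == 0:
        raise ValueError("occurrences must be nonempty")
    dist = _distance_to_occurrences_km(occ, env)
    mask = (dist <= buffer_km) & env.valid_mask()
    return TrainingRegion(mask=mask, buffer_km=buffer_km)


# ---------------------------------------------------------------------------
# pseudo-absences
# ---------------------------------------------------------------------------

@dataclass
class PseudoAbsenceSet:
    """Sampled pseudo-absence points with the strategy that produced them."""

    points: pd.DataFrame          # lon, lat
    strategy: str                 # "GE" or "ES"
    replicate_id: int
    n_points: int
    seed: int
    exclusion_km: float | None = None
    envelope: "PresenceEnvelope | None" = None


def _sample_cells(mask: np.ndarray, env: EnvGridStack, n: int,
                  rng: np.random.Generator) -> pd.DataFrame:
    eligible = np.flatnonzero(mask.ravel())
    if eligible.size < n:
        raise ValueError(
            f"requested {n} pseudo-absences but only {eligible.size} "
            f"eligible cells exist")
    chosen = rng.choice(eligible, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, env.shape)
    x, y = env.transform.cell_center(rows, cols)
    return pd.DataFrame({"lon": x, "lat": y})


def sample_pa_ge(region: TrainingRegion, occ: pd.DataFrame, env: EnvGridStack,
                 exclusion_km: float, n: int,
                 replicate_seed: int = 0, replicate_id: int = 0) -> PseudoAbsenceSet:
    """Geographic-exclusion pseudo-absences: uniform draws from the training
    region outside ``exclusion_km`` disks around every occurrence."""
    dist = _distance_to_occurrences_km(occ, env)
    eligible = region.mask & (dist > exclusion_km)
    rng = np.random.default_rng(replicate_seed)
    pts = _sample_cells(eligible, env, n, rng)
    return PseudoAbsenceSet(pts, "GE", replicate_id, n, replicate_seed,
                            exclusion_km=exclusion_km)


@dataclass
class PresenceEnvelope:
    """Robust ellipsoidal envelope of presence environments.

    A vector is 'similar' iff its squared Mahalanobis distance to the robust
    location is at or below the chi-squared(dim) quantile ``cutoff``.
    """

    location: np.ndarray
    scatter: np.ndarray
    cutoff: float
    quantile: float
    _precision: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self._precision is None:
            try:
                self._precision = np.linalg.inv(self.scatter)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    "singular presence scatter matrix; drop collinear "
                    "environmental variables first") from exc

    def squared_distance(self, values: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(np.asarray(values, float)) - self.location
        return np.einsum("ij,jk,ik->i", d, self._precision, d)

    def contains(self, values: np.ndarray) -> np.ndarray:
        return self.squared_distance(values) <= self.cutoff


def fit_presence_envelope(presence_env: np.ndarray,
                          quantile: float = 0.95) -> PresenceEnvelope:
    """Fit the robust presence envelope (MCD location/scatter)."""
    from sklearn.covariance import MinCovDet

    X = np.asarray(presence_env, float)
    X = X[np.isfinite(X).all(axis=1)]
    dim = X.shape[1]
    if len(X) < dim + 2:
        raise ValueError(f"need at least {dim + 2} presence vectors")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcd = MinCovDet(random_state=0).fit(X)
    cov = mcd.covariance_
    if np.linalg.matrix_rank(cov) < dim:
        raise ValueError("singular presence scatter matrix; drop collinear "
                         "environmental variables first")
    return PresenceEnvelope(location=mcd.location_, scatter=cov,
                            cutoff=float(stats.chi2.ppf(quantile, dim)),
                            quantile=quantile)


def sample_pa_es(region: TrainingRegion, envelope: PresenceEnvelope,
                 env: EnvGridStack, n: int,
                 replicate_seed: int = 0, replicate_id: int = 0,
                 layer_names: list[str] | None = None) -> PseudoAbsenceSet:
    """Environmental-similarity pseudo-absences: uniform draws from in-region
    cells whose environment falls *outside* the presence envelope."""
    sub = env.subset(layer_names) if layer_names else env
    vals = sub.as_array().reshape(sub.n_layers, -1).T
    outside = np.zeros(vals.shape[0], bool)
    finite = np.isfinite(vals).all(axis=1)
    outside[finite] = ~envelope.contains(vals[finite])
    eligible = region.mask & outside.reshape(env.shape)
    if not eligible.any():
        raise ValueError("presence envelope accepts the whole region; "
                         "no environmentally dissimilar cells to sample")
    rng = np.random.default_rng(replicate_seed)
    pts = _sample_cells(eligible, env, n, rng)
    return PseudoAbsenceSet(pts, "ES", replicate_id, n, replicate_seed,
                            envelope=envelope)


# ---------------------------------------------------------------------------
# spatial autocorrelation range & block partition
# ---------------------------------------------------------------------------

def estimate_autocorr_range_km(env: EnvGridStack, mask: np.ndarray | None = None,
                               n_cells: int = 2000, seed: int = 0,
                               n_bins: int = 30) -> float:
    """Median across layers of the effective range (km) of an exponential
    variogram fitted to sampled cell pairs."""
    valid = env.valid_mask() if mask is None else (np.asarray(mask, bool)
                                                   & env.valid_mask())
    cells = np.flatnonzero(valid.ravel())
    if cells.size < 10:
        raise ValueError("too few valid cells for variogram estimation")
    rng = np.random.default_rng(seed)
    if cells.size > n_cells:
        cells = rng.choice(cells, n_cells, replace=False)
    rows, cols = np.unravel_index(cells, env.shape)
    x, y = env.transform.cell_center(rows, cols)
    d = cross_distance_km(x, y, x, y, env.is_geographic)
    iu = np.triu_indices(len(x), k=1)
    dd = d[iu]
    max_lag = np.quantile(dd, 0.5)
    bins = np.linspace(0, max_lag, n_bins + 1)
    cell_km = min(env.transform.dx, env.transform.dy)

    ranges = []
    for name in env.layer_names:
        v = env.layers[name].ravel()[np.ravel_multi_index((rows, cols), env.shape)]
        g = 0.5 * (v[iu[0]] - v[iu[1]]) ** 2
        sel = (dd > 0) & (dd < max_lag)
        bi = np.digitize(dd[sel], bins)
        bd, bg = [], []
        for i in range(1, n_bins + 1):
            m = bi == i
            if m.sum() >= 10:
                bd.append(dd[sel][m].mean())
                bg.append(g[sel][m].mean())
        if len(bd) < 4:
            continue
        bd, bg = np.array(bd), np.array(bg)
        try:
            p, _ = curve_fit(lambda h, s, a: s * (1 - np.exp(-3 * h / a)),
                             bd, bg, p0=[v.var(), max(max_lag / 5, cell_km)],
                             bounds=([0, cell_km * 1e-3], [np.inf, np.inf]),
                             maxfev=10000)
            ranges.append(p[1])
        except RuntimeError:
            continue
    if not ranges:
        return cell_km
    return float(max(np.median(ranges), cell_km))


@dataclass
class BlockPartition:
    """Square spatial blocks assigned to k folds, balanced on presences."""

    block_size_km: float
    k: int
    origin: tuple[float, float]          # top-left of block grid
    n_block_rows: int
    n_block_cols: int
    fold_of_block: np.ndarray            # (n_block_rows * n_block_cols,)
    occurrence_folds: np.ndarray
    fold_presence_counts: np.ndarray
    fallback_strips: bool = False

    def block_of(self, x, y) -> np.ndarray:
        bx = np.floor((np.asarray(x, float) - self.origin[0])
                      / self.block_size_km).astype(int)
        by = np.floor((self.origin[1] - np.asarray(y, float))
                      / self.block_size_km).astype(int)
        bx = np.clip(bx, 0, self.n_block_cols - 1)
        by = np.clip(by, 0, self.n_block_rows - 1)
        return by * self.n_block_cols + bx

    def fold_of(self, x, y) -> np.ndarray:
        return self.fold_of_block[self.block_of(x, y)]


def make_block_partition(occ: pd.DataFrame, env: EnvGridStack,
                         region: TrainingRegion, k: int = 4,
                         block_size_km: float | None = None,
                         seed: int = 0) -> BlockPartition:
    """Tile square blocks (sized by the spatial autocorrelation range) over
    the region and assign them to ``k`` folds, greedily balancing presence
    counts (largest block first into the currently smallest fold).

    If the block size exceeds the region extent the partition falls back to
    ``k`` vertical strips with a warning.
    """
    if not region.mask.any():
        raise ValueError("empty training region")
    if block_size_km is None:
        block_size_km = estimate_autocorr_range_km(env, region.mask, seed=seed)
    rng = np.random.default_rng(seed)
    rows_m, cols_m = np.nonzero(region.mask)
    x_cells, y_cells = env.transform.cell_center(rows_m, cols_m)
    x_min, x_max = x_cells.min(), x_cells.max()
    y_min, y_max = y_cells.min(), y_cells.max()
    extent = max(x_max - x_min, y_max - y_min) + min(env.transform.dx,
                                                     env.transform.dy)
    fallback = False
    if block_size_km >= extent:
        log.warning("block size %.1f km exceeds region extent %.1f km; "
                    "falling back to %d vertical strips", block_size_km,
                    extent, k)
        fallback = True
        block_size_km = max((x_max - x_min) / k,
                            min(env.transform.dx, env.transform.dy))

    origin = (x_min - 1e-9, y_max + 1e-9)
    n_bc = max(int(np.ceil((x_max - origin[0]) / block_size_km)) + 1, 1)
    n_br = 1 if fallback else max(
        int(np.ceil((origin[1] - y_min) / block_size_km)) + 1, 1)

    part = BlockPartition(block_size_km, k, origin, n_br, n_bc,
                          fold_of_block=np.zeros(n_br * n_bc, int),
                          occurrence_folds=np.zeros(len(occ), int),
                          fold_presence_counts=np.zeros(k, int),
                          fallback_strips=fallback)
    if fallback:
        part.n_block_rows = 1

    occ_blocks = part.block_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    counts = np.bincount(occ_blocks, minlength=n_br * n_bc)

    order = np.argsort(-(counts + rng.random(counts.size)))  # random ties
    fold_tot = np.zeros(k, float)
    fold_of_block = np.zeros(n_br * n_bc, int)
    for b in order:
        # ties between folds broken at random for re-randomizable assignments
        f = int(np.argmin(fold_tot + 1e-9 * rng.random(k)))
        fold_of_block[b] = f
        fold_tot[f] += counts[b]
    part.fold_of_block = fold_of_block
    part.occurrence_folds = fold_of_block[occ_blocks]
    part.fold_presence_counts = np.bincount(part.occurrence_folds, minlength=k)
    if part.fold_presence_counts.max() > 2 * max(part.fold_presence_counts.min(), 1):
        log.warning("block folds are unbalanced: presence counts %s",
                    part.fold_presence_counts.tolist())
    return part


def make_random_partition(occ: pd.DataFrame, pa: pd.DataFrame,
                          test_fraction: float = 0.25, runs: int = 10,
                          seed: int = 0) -> list[dict]:
    """Seeded stratified 75/25 splits; one dict of index arrays per run."""
    if len(occ) < 4:
        raise ValueError("need at least 4 presences")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(runs):
        occ_idx = rng.permutation(len(occ))
        pa_idx = rng.permutation(len(pa))
        n_occ_test = max(int(round(test_fraction * len(occ))), 1)
        n_pa_test = max(int(round(test_fraction * len(pa))), 1)
        splits.append({
            "occ_test": np.sort(occ_idx[:n_occ_test]),
            "occ_train": np.sort(occ_idx[n_occ_test:]),
            "pa_test": np.sort(pa_idx[:n_pa_test]),
            "pa_train": np.sort(pa_idx[n_pa_test:]),
        })
    return splits


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def expand_features(values: np.ndarray) -> np.ndarray:
    """Linear + quadratic + pairwise-product feature expansion."""
    X = np.atleast_2d(np.asarray(values, float))
    cols = [X, X ** 2]
    n = X.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            cols.append((X[:, i] * X[:, j])[:, None])
    return np.hstack(cols)


DEFAULT_PENALTY_GRID = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0)


@dataclass
class FittedSDM:
    """Penalized presence-background logistic model on expanded features."""

    coef: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    layer_names: list[str]
    penalty_C: float
    fold_id: int = 0
    pa_replicate_id: int = 0

    def predict_values(self, env_values: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for raw env-value rows (NaN rows -> NaN)."""
        from scipy.special import expit
        V = np.atleast_2d(np.asarray(env_values, float))
        out = np.full(V.shape[0], np.nan)
        ok = np.isfinite(V).all(axis=1)
        if ok.any():
            F = (expand_features(V[ok]) - self.feature_mean) / self.feature_sd
            out[ok] = expit(F @ self.coef + self.intercept)
        return out

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "layer_names": list(self.layer_names),
            "penalty_C": self.penalty_C,
            "fold_id": self.fold_id,
            "pa_replicate_id": self.pa_replicate_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedSDM":
        return cls(coef=np.asarray(d["coef"], float),
                   intercept=float(d["intercept"]),
                   feature_mean=np.asarray(d["feature_mean"], float),
                   feature_sd=np.asarray(d["feature_sd"], float),
                   layer_names=list(d["layer_names"]),
                   penalty_C=float(d["penalty_C"]),
                   fold_id=int(d["fold_id"]),
                   pa_replicate_id=int(d["pa_replicate_id"]))

    def predict_grid(self, env: EnvGridStack) -> np.ndarray:
        missing = [n for n in self.layer_names if n not in env.layers]
        if missing:
            raise ValueError(f"target grid lacks required layers: {missing}")
        sub = env.subset(self.layer_names)
        vals = sub.as_array().reshape(sub.n_layers, -1).T
        if np.isfinite(env.nodata):
            vals = np.where(vals == env.nodata, np.nan, vals)
        return self.predict_values(vals).reshape(env.shape)


def fit_sdm(train_presence_env: np.ndarray, train_pa_env: np.ndarray,
            layer_names: list[str] | None = None,
            penalty_grid=DEFAULT_PENALTY_GRID, seed: int = 0,
            fold_id: int = 0, pa_replicate_id: int = 0) -> FittedSDM:
    """Fit the L1-penalized presence-background logistic model.

    Pseudo-absences are down-weighted so total class weights are equal. The
    penalty is chosen by binomial deviance on an internal 80/20 split of the
    training data, then the model is refit on all of it.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import log_loss

    P = np.asarray(train_presence_env, float)
    A = np.asarray(train_pa_env, float)
    P = P[np.isfinite(P).all(axis=1)]
    A = A[np.isfinite(A).all(axis=1)]
    if len(P) == 0 or len(A) == 0:
        raise ValueError("both classes must be nonempty")
    if layer_names is None:
        layer_names = [f"env{i + 1}" for i in range(P.shape[1])]
    X = expand_features(np.vstack([P, A]))
    y = np.concatenate([np.ones(len(P)), np.zeros(len(A))])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (X - mean) / sd

    rng = np.random.default_rng(seed)
    grid = sorted(set(float(c) for c in penalty_grid))
    best_C = grid[0]
    if len(grid) > 1:
        idx = rng.permutation(len(y))
        n_val = max(int(0.2 * len(y)), 2)
        val, tr = idx[:n_val], idx[n_val:]
        # keep both classes in each part; fall back to full-data fit otherwise
        if len(np.unique(y[tr])) == 2 and len(np.unique(y[val])) == 2:
            best_loss = np.inf
            for C in grid:
                m = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                       class_weight="balanced", max_iter=2000,
                                       random_state=0)
                m.fit(Xs[tr], y[tr])
                w_val = np.where(y[val] == 1, 1.0,
                                 (y[tr] == 1).sum() / max((y[tr] == 0).sum(), 1))
                loss = log_loss(y[val], m.predict_proba(Xs[val])[:, 1],
                                sample_weight=w_val, labels=[0.0, 1.0])
                if loss < best_loss:
                    best_loss, best_C = loss, C
    final = LogisticRegression(l1_ratio=1.0, C=best_C, solver="liblinear",
                               class_weight="balanced", max_iter=2000,
                               random_state=0)
    final.fit(Xs, y)
    return FittedSDM(coef=final.coef_.ravel(), intercept=float(final.intercept_[0]),
                     feature_mean=mean, feature_sd=sd, layer_names=list(layer_names),
                     penalty_C=best_C, fold_id=fold_id,
                     pa_replicate_id=pa_replicate_id)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    auc_cal: float
    auc_val: float
    tss_cal: float
    tss_val: float
    tss_threshold: float


def rank_auc(pred_presence: np.ndarray, pred_absence: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic; ties count one half."""
    p = np.asarray(pred_presence, float)
    a = np.asarray(pred_absence, float)
    if len(p) == 0 or len(a) == 0:
        raise ValueError("both classes must be nonempty")
    ranks = stats.rankdata(np.concatenate([p, a]))
    r1 = ranks[:len(p)].sum()
    return float((r1 - len(p) * (len(p) + 1) / 2) / (len(p) * len(a)))


def max_tss(pred_presence: np.ndarray, pred_absence: np.ndarray
            ) -> tuple[float, float]:
    """Max of sensitivity + specificity - 1 over the fixed threshold grid;
    returns (tss, maximizing threshold)."""
    p = np.asarray(pred_presence, float)[:, None]
    a = np.asarray(pred_absence, float)[:, None]
    thr = TSS_THRESHOLDS[None, :]
    sens = (p >= thr).mean(axis=0)
    spec = (a < thr).mean(axis=0)
    tss = sens + spec - 1.0
    i = int(np.argmax(tss))
    return float(tss[i]), float(TSS_THRESHOLDS[i])


def evaluate(model: FittedSDM,
             cal_presence_env: np.ndarray, cal_pa_env: np.ndarray,
             val_presence_env: np.ndarray, val_pa_env: np.ndarray) -> EvalResult:
    """Calibration and validation AUC/TSS for a fitted model."""
    def preds(V):
        out = model.predict_values(V)
        out = out[np.isfinite(out)]
        if len(out) == 0:
            raise ValueError("a class has no scorable records")
        return out

    pc, ac = preds(cal_presence_env), preds(cal_pa_env)
    pv, av = preds(val_presence_env), preds(val_pa_env)
    tss_cal, _ = max_tss(pc, ac)
    tss_val, thr = max_tss(pv, av)
    return EvalResult(auc_cal=rank_auc(pc, ac), auc_val=rank_auc(pv, av),
                      tss_cal=tss_cal, tss_val=tss_val, tss_threshold=thr)


# ---------------------------------------------------------------------------
# the model matrix
# ---------------------------------------------------------------------------

@dataclass
class ModelMatrixConfig:
    """One species' model-matrix recipe.

    ``variable_groups`` maps group name to layer-name list (mirroring
    climate/soil/landcover groupings); each combination of variable group x
    pseudo-absence strategy x cross-validation strategy yields
    ``cv_runs x pa_replicates`` fitted models (50 under the defaults).
    """

    species: str
    variable_groups: dict[str, list[str]]
    pa_strategies: tuple[str, ...] = ("GE", "ES")
    cv_strategies: tuple[str, ...] = ("random", "block")
    pa_n: int = 1000
    pa_exclusion_km: float = 10.0
    pa_replicates: int = 5
    es_quantile: float = 0.95
    cv_runs: int = 10
    cv_k: int = 4
    test_fraction: float = 0.25
    buffer_km: float = 200.0
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID
    block_size_km: float | None = None
    master_seed: int = 0


def _stage_seed(master: int, *key: int) -> int:
    """Deterministic fan-out of the master seed (documented counter scheme)."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_model_matrix(occ: pd.DataFrame, env: EnvGridStack,
                     config: ModelMatrixConfig,
                     keep_models: bool = True) -> tuple[list, pd.DataFrame]:
    """Fit the full model matrix for one species.

    For each variable group x PA strategy x CV strategy combination this
    fits ``cv_runs`` cross-validation runs against each of
    ``pa_replicates`` pseudo-absence replicate sets and evaluates every
    model on its held-out data. The block strategy cycles its k spatial
    folds across runs, re-randomizing the block-to-fold assignment after
    each full cycle; the random strategy draws independent stratified
    splits. Fully deterministic given ``config.master_seed``.

    Returns (models, metrics) where metrics has one row per fitted model.
    """
    region = build_training_region(occ, env, config.buffer_km)
    occ_xy = occ[["lon", "lat"]].to_numpy()
    models, rows = [], []

    for g_i, (group, layers) in enumerate(config.variable_groups.items()):
        sub = env.subset(layers)
        occ_env = sub.sample(occ_xy[:, 0], occ_xy[:, 1])
        # block size estimated once per variable group (it depends only on
        # the layers and the region, not on the replicate)
        block_size = config.block_size_km
        if block_size is None and "block" in config.cv_strategies:
            block_size = estimate_autocorr_range_km(
                sub, region.mask, seed=_stage_seed(config.master_seed, 0, g_i))
        envelope = (fit_presence_envelope(occ_env, config.es_quantile)
                    if "ES" in config.pa_strategies else None)
        for s_i, strategy in enumerate(config.pa_strategies):
            # pseudo-absence replicate sets
            pa_sets = []
            for rep in range(config.pa_replicates):
                seed = _stage_seed(config.master_seed, 1, g_i, s_i, rep)
                if strategy == "GE":
                    pa = sample_pa_ge(region, occ, env, config.pa_exclusion_km,
                                      config.pa_n, seed, rep)
                elif strategy == "ES":
                    pa = sample_pa_es(region, envelope, env, config.pa_n, seed,
                                      rep, layer_names=layers)
                else:
                    raise ValueError(f"unknown PA strategy {strategy!r}")
                pa_env = sub.sample(pa.points["lon"].to_numpy(),
                                    pa.points["lat"].to_numpy())
                pa_sets.append((pa, pa_env))
            for c_i, cv in enumerate(config.cv_strategies):
                for rep, (pa, pa_env) in enumerate(pa_sets):
                    pa_xy = pa.points[["lon", "lat"]].to_numpy()
                    for run in range(config.cv_runs):
                        seed = _stage_seed(config.master_seed, 2, g_i, s_i,
                                           c_i, rep, run)
                        if cv == "random":
                            split = make_random_partition(
                                occ, pa.points, config.test_fraction, 1,
                                seed)[0]
                        elif cv == "block":
                            # re-randomize assignment each full k-fold cycle
                            part_seed = _stage_seed(config.master_seed, 3,
                                                    g_i, s_i, c_i, rep,
                                                    run // config.cv_k)
                            part = make_block_partition(
                                occ, sub, region, config.cv_k,
                                block_size, part_seed)
                            fold = run % config.cv_k
                            occ_folds = part.occurrence_folds
                            pa_folds = part.fold_of(pa_xy[:, 0], pa_xy[:, 1])
                            split = {
                                "occ_test": np.flatnonzero(occ_folds == fold),
                                "occ_train": np.flatnonzero(occ_folds != fold),
                                "pa_test": np.flatnonzero(pa_folds == fold),
                                "pa_train": np.flatnonzero(pa_folds != fold),
                            }
                        else:
                            raise ValueError(f"unknown CV strategy {cv!r}")
                        if (min(len(split["occ_train"]), len(split["occ_test"]),
                                len(split["pa_train"]), len(split["pa_test"]))
                                == 0):
                            log.warning("skipping empty fold (%s %s run %d)",
                                        group, cv, run)
                            continue
                        model = fit_sdm(occ_env[split["occ_train"]],
                                        pa_env[split["pa_train"]],
                                        layers, config.penalty_grid,
                                        seed=seed, fold_id=run,
                                        pa_replicate_id=rep)
                        ev = evaluate(model,
                                      occ_env[split["occ_train"]],
                                      pa_env[split["pa_train"]],
                                      occ_env[split["occ_test"]],
                                      pa_env[split["pa_test"]])
                        if keep_models:
                            models.append(model)
                        rows.append({
                            "species": config.species,
                            "variable_group": group,
                            "pa_strategy": strategy,
                            "cv_strategy": cv,
                            "pa_replicate": rep,
                            "cv_run": run,
                            "auc_cal": ev.auc_cal, "auc_val": ev.auc_val,
                            "tss_cal": ev.tss_cal, "tss_val": ev.tss_val,
                            "tss_threshold": ev.tss_threshold,
                            "penalty_C": model.penalty_C,
                        })
    return models, pd.DataFrame(rows)
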