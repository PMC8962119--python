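"""Pedigree-based mixed models: additive relationship matrix, REML fitting
of ``y = Xb + Zu + xi + eta`` under candidate spatial residual structures,
AICc model comparison, heritability and BLUP breeding values.

``u`` is the additive genetic effect with covariance ``sigma2_a * A`` (A
from the pedigree via the tabular method), ``xi`` the spatially dependent
residual with covariance ``sigma2_xi * R(structure)`` and ``eta`` the
independent residual (nugget) with variance ``sigma2_eta``. Fixed effects
default to an intercept. All linear algebra is dense (n of a few hundred).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .parentage import Pedigree
from .spatial import (
    AR1_KINDS,
    GridAssignment,
    SpatialStructure,
    build_correlation_matrix,
)

__all__ = [
    "RelationshipMatrix",
    "SpatialModelSpec",
    "FitResult",
    "OptimizerConfig",
    "ModelData",
    "build_A",
    "reml_loglik",
    "fit",
    "aicc",
    "compare_models",
    "blup",
    "heritability",
    "heritability_from_components",
    "rank_selection",
    "default_structures",
]


# ---------------------------------------------------------------------------
# Relationship matrix
# ---------------------------------------------------------------------------


@dataclass
class RelationshipMatrix:
    """Additive (numerator) relationship matrix over pedigree members."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self._index = {i: k for k, i in enumerate(self.ids)}

    def index(self, individual: str) -> int:
        return self._index[individual]

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = [self._index[i] for i in ids]
        return self.matrix[np.ix_(idx, idx)]


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Tabular (recursive) additive relationship matrix.

    Founders are unrelated and non-inbred; unknown parents are treated as
    distinct unrelated founders (so maternal half-sibs with unknown sires
    get A = 0.25 and dam-offspring pairs A = 0.5). Raises on cyclic
    pedigrees (via the Pedigree topological order).
    """
    order = pedigree.topological_order()
    n = len(order)
    pos = {ind: k for k, ind in enumerate(order)}
    a = np.zeros((n, n))
    for k, ind in enumerate(order):
        dam, sire = pedigree.parents[ind]
        di = pos[dam] if dam is not None else None
        si = pos[sire] if sire is not None else None
        f = 0.5 * a[di, si] if (di is not None and si is not None) else 0.0
        a[k, k] = 1.0 + f
        for j in range(k):
            val = 0.0
            if di is not None:
                val += 0.5 * a[j, di]
            if si is not None:
                val += 0.5 * a[j, si]
            a[j, k] = a[k, j] = val
    # return in the pedigree's own id order
    ids = pedigree.ids
    idx = [pos[i] for i in ids]
    return RelationshipMatrix(ids=ids, matrix=a[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Model specification and data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialModelSpec:
    """Which terms enter the mixed model.

    ``genetic``: "animal" (individual effect via A), "family" (dam as an
    i.i.d. random effect) or None (no genetic term). ``structure``: one
    spatial correlation family for xi, or None for the purely independent
    residual. ``label`` names the model in comparison tables.
    """

    genetic: str | None = "animal"
    structure: SpatialStructure | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.genetic not in ("animal", "family", None):
            raise ValueError("genetic must be 'animal', 'family' or None")
        if self.genetic is None and self.structure is None:
            raise ValueError("model needs at least one random term besides the nugget")
        if self.label is None:
            parts = []
            if self.genetic:
                parts.append(self.genetic)
            if self.structure is not None:
                parts.append(self.structure.kind)
            object.__setattr__(self, "label", "+".join(parts))

    @property
    def n_variance_params(self) -> int:
        k = 1  # nugget
        if self.genetic is not None:
            k += 1
        if self.structure is not None:
            k += 1
        return k

    @property
    def n_structure_params(self) -> int:
        return self.structure.n_params if self.structure is not None else 0


@dataclass
class ModelData:
    """Phenotyped individuals: ids, response vector and coordinates."""

    ids: list[str]
    y: np.ndarray
    coords: dict[str, tuple[float, float]] | None = None
    X: np.ndarray | None = None  # defaults to an intercept column

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.ids) != self.y.size:
            raise ValueError("ids and y length mismatch")
        if self.X is not None:
            self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
            if self.X.shape[0] != self.y.size:
                raise ValueError("X row count must match y")

    def design(self) -> np.ndarray:
        return self.X if self.X is not None else np.ones((self.y.size, 1))

    @classmethod
    def from_records(cls, records) -> "ModelData":
        return cls(
            ids=[t.id for t in records],
            y=np.array([t.dbh for t in records]),
            coords={t.id: (t.x, t.y) for t in records},
        )


@dataclass
class OptimizerConfig:
    n_starts: int = 3
    seed: int = 0
    maxiter: int = 400
    tol: float = 1e-8


@dataclass
class FitResult:
    spec: SpatialModelSpec
    params: dict[str, float]
    beta: float
    loglik: float
    k: int
    n: int
    aicc: float
    h2: float | None
    se: dict[str, float]
    converged: bool
    n_starts_converged: int
    message: str
    data_ids: list[str] = field(default_factory=list, repr=False)

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.spec.label,
            "params": self.params,
            "intercept": self.beta,
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "h2": self.h2,
            "se": self.se,
            "converged": self.converged,
            "message": self.message,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


def _chol_with_jitter(v: np.ndarray) -> tuple[np.ndarray, float]:
    scale = float(np.mean(np.diag(v)))
    for jit in _JITTERS:
        try:
            return linalg.cholesky(v + jit * scale * np.eye(v.shape[0]), lower=True), jit
        except linalg.LinAlgError:
            continue
    raise linalg.LinAlgError("V not positive definite even with jitter 1e-6")


def _genetic_covariance(
    spec: SpatialModelSpec, data: ModelData, A: RelationshipMatrix | None, pedigree: Pedigree | None
) -> np.ndarray | None:
    if spec.genetic is None:
        return None
    if spec.genetic == "animal":
        if A is None:
            raise ValueError("animal model needs a relationship matrix")
        return A.submatrix(data.ids)
    # family: dam identity => block covariance Zf Zf' (1 within family)
    if pedigree is None:
        raise ValueError("family model needs a pedigree to identify dams")
    dams = [pedigree.dam(i) if i in pedigree.parents else None for i in data.ids]
    n = len(data.ids)
    g = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if dams[i] is not None and dams[i] == dams[j]:
                g[i, j] = 1.0
    np.fill_diagonal(g, 1.0)
    return g


def _structure_matrix(
    spec: SpatialModelSpec, params: dict[str, float], data: ModelData, grid: GridAssignment | None
) -> np.ndarray | None:
    st = spec.structure
    if st is None:
        return None
    if st.kind in AR1_KINDS:
        if grid is None:
            raise ValueError(f"{st.kind} structure needs a grid assignment")
        if st.kind == "ar1xar1":
            st = replace(st, rho_row=params["rho_row"], rho_col=params["rho_col"])
        else:
            st = replace(st, rho=params["rho"])
        return build_correlation_matrix(st, grid, observed_ids=data.ids)
    st = replace(st, r=params["r"])
    if data.coords is None:
        raise ValueError("distance-based structures need coordinates in ModelData")
    return build_correlation_matrix(st, data.coords, observed_ids=data.ids)


def reml_loglik(
    params: dict[str, float],
    spec: SpatialModelSpec,
    data: ModelData,
    A: RelationshipMatrix | None = None,
    grid: GridAssignment | None = None,
    pedigree: Pedigree | None = None,
    _cache: dict | None = None,
) -> float:
    """Restricted log-likelihood of ``y`` under ``N(Xb, V)`` with the
    intercept profiled out by GLS.

    ``V = sigma2_a * G + sigma2_xi * R + sigma2_eta * I`` with G the
    relationship submatrix (or family blocks) and R the spatial correlation
    matrix. Returns ``-0.5 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| +
    y'Py ]``. Raises on non-positive-definite V (after a bounded jitter
    escalation) carrying the offending parameters.
    """
    y = data.y
    n = y.size
    x = data.design()
    p = x.shape[1]
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("fixed-effect design matrix is rank deficient")
    v = params.get("sigma2_eta", 0.0) * np.eye(n)
    if spec.genetic is not None:
        g = (
            _cache["G"]
            if _cache is not None and "G" in _cache
            else _genetic_covariance(spec, data, A, pedigree)
        )
        if _cache is not None:
            _cache["G"] = g
        v = v + params["sigma2_a"] * g
    if spec.structure is not None:
        r = _structure_matrix(spec, params, data, grid)
        v = v + params["sigma2_xi"] * r
    try:
        cho, _ = _chol_with_jitter(v)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(f"V not positive definite at params {params}") from exc
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(cho))))
    vi_x = linalg.cho_solve((cho, True), x)
    vi_y = linalg.cho_solve((cho, True), y)
    xtvix = x.T @ vi_x
    logdet_xtvix = float(np.log(np.linalg.det(xtvix)))
    beta = np.linalg.solve(xtvix, x.T @ vi_y)
    quad = float(y @ vi_y - beta.T @ (x.T @ vi_y))
    return -0.5 * ((n - p) * math.log(2 * math.pi) + logdet_v + logdet_xtvix + quad)


# parameter transforms: variances on log scale, correlations on scaled
# arctanh, ranges on log scale
_RHO_MAX = 0.999


def _param_names(spec: SpatialModelSpec) -> list[str]:
    names = []
    if spec.genetic is not None:
        names.append("sigma2_a")
    if spec.structure is not None:
        names.append("sigma2_xi")
    names.append("sigma2_eta")
    if spec.structure is not None:
        if spec.structure.kind == "ar1xar1":
            names += ["rho_row", "rho_col"]
        elif spec.structure.kind == "ar1":
            names.append("rho")
        else:
            names.append("r")
    return names


def _to_natural(theta: np.ndarray, names: list[str]) -> dict[str, float]:
    out = {}
    for t, name in zip(theta, names):
        if name.startswith("sigma2") or name == "r":
            out[name] = float(np.exp(t))
        else:
            out[name] = float(_RHO_MAX * np.tanh(t))
    return out


def _to_transformed(params: dict[str, float], names: list[str]) -> np.ndarray:
    vals = []
    for name in names:
        v = params[name]
        if name.startswith("sigma2") or name == "r":
            vals.append(math.log(max(v, 1e-12)))
        else:
            vals.append(math.atanh(np.clip(v / _RHO_MAX, -0.999999, 0.999999)))
    return np.array(vals)


def fit(
    spec: SpatialModelSpec,
    data: ModelData,
    A: RelationshipMatrix | None = None,
    grid: GridAssignment | None = None,
    pedigree: Pedigree | None = None,
    optimizer_config: OptimizerConfig | None = None,
) -> FitResult:
    """Maximize the restricted likelihood over variance components (log
    scale) and correlation/range parameters (scaled arctanh / log scale).

    Runs ``n_starts`` seeded multi-starts (first start at an equal variance
    split, the rest perturbed) and keeps the best converged optimum.
    Approximate standard errors come from the observed information (numeric
    Hessian of the REML log-likelihood in natural parameters). Deterministic
    for fixed data and optimizer seed.
    """
    cfg = optimizer_config or OptimizerConfig()
    names = _param_names(spec)
    y = data.y
    n = y.size
    k = 1 + spec.n_variance_params + spec.n_structure_params
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    vary = float(np.var(y, ddof=1))
    n_var = spec.n_variance_params
    base: dict[str, float] = {}
    for name in names:
        if name.startswith("sigma2"):
            base[name] = vary / n_var
        elif name in ("rho", "rho_row", "rho_col"):
            base[name] = 0.5
        elif name == "r":
            base[name] = _median_distance(data)
    cache: dict = {}

    def objective(theta: np.ndarray) -> float:
        params = _to_natural(theta, names)
        try:
            return -reml_loglik(params, spec, data, A, grid, pedigree, _cache=cache)
        except (linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e10

    rng = np.random.default_rng(cfg.seed)
    starts = [_to_transformed(base, names)]
    for _ in range(cfg.n_starts - 1):
        pert = {
            name: (
                base[name] * float(rng.lognormal(0.0, 0.8))
                if name.startswith("sigma2") or name == "r"
                else float(rng.uniform(-0.8, 0.8))
            )
            for name in names
        }
        starts.append(_to_transformed(pert, names))
    best = None
    n_conv = 0
    for theta0 in starts:
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=[(-20.0, 20.0)] * len(names),
            options={"maxiter": cfg.maxiter, "ftol": cfg.tol, "gtol": 1e-7},
        )
        if res.fun < 1e9:
            n_conv += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(
            f"all {cfg.n_starts} optimizer starts failed for model {spec.label}"
        )
    params = _to_natural(best.x, names)
    ll = -float(best.fun)
    # intercept at the optimum
    beta = _gls_intercept(params, spec, data, A, grid, pedigree, cache)
    se = _observed_information_se(params, names, spec, data, A, grid, pedigree, cache)
    h2 = None
    if spec.genetic is not None:
        h2 = heritability_from_components(
            params.get("sigma2_a", 0.0),
            params.get("sigma2_xi", 0.0),
            params.get("sigma2_eta", 0.0),
        )
    return FitResult(
        spec=spec,
        params=params,
        beta=beta,
        loglik=ll,
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        h2=h2,
        se=se,
        converged=bool(best.success or best.fun < 1e9),
        n_starts_converged=n_conv,
        message=str(best.message),
        data_ids=list(data.ids),
    )


def _median_distance(data: ModelData) -> float:
    if data.coords is None:
        return 1.0
    pts = np.array([data.coords[i] for i in data.ids])
    sub = pts[:: max(1, len(pts) // 80)]
    from scipy.spatial.distance import pdist

    d = pdist(sub)
    med = float(np.median(d)) if d.size else 1.0
    return med if med > 0 else 1.0


def _gls_intercept(params, spec, data, A, grid, pedigree, cache) -> float:
    n = data.y.size
    x = np.ones((n, 1))
    v = params.get("sigma2_eta", 0.0) * np.eye(n)
    if spec.genetic is not None:
        v = v + params["sigma2_a"] * cache["G"]
    if spec.structure is not None:
        v = v + params["sigma2_xi"] * _structure_matrix(spec, params, data, grid)
    cho, _ = _chol_with_jitter(v)
    vi_x = linalg.cho_solve((cho, True), x)
    vi_y = linalg.cho_solve((cho, True), data.y)
    return float(((x.T @ vi_y) / (x.T @ vi_x)).item())


def _observed_information_se(params, names, spec, data, A, grid, pedigree, cache) -> dict[str, float]:
    """SEs from a central-difference Hessian of the REML log-likelihood in
    natural parameter space; NaN where the information is not invertible."""
    theta = np.array([params[name] for name in names])
    steps = np.array(
        [max(1e-5, 1e-4 * abs(v)) if name.startswith("sigma2") or name == "r" else 1e-4
         for v, name in zip(theta, names)]
    )

    def ll_at(vec: np.ndarray) -> float:
        p = dict(zip(names, vec))
        for name in names:
            if name in ("rho", "rho_row", "rho_col"):
                p[name] = float(np.clip(p[name], -_RHO_MAX, _RHO_MAX))
            else:
                p[name] = max(p[name], 1e-12)
        try:
            return reml_loglik(p, spec, data, A, grid, pedigree, _cache=cache)
        except (linalg.LinAlgError, ValueError):
            return -np.inf

    m = len(names)
    hess = np.full((m, m), np.nan)
    f0 = ll_at(theta)
    ok = math.isfinite(f0)
    if ok:
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m)
                ej = np.zeros(m)
                ei[i] = steps[i]
                ej[j] = steps[j]
                fpp = ll_at(theta + ei + ej)
                fpm = ll_at(theta + ei - ej)
                fmp = ll_at(theta - ei + ej)
                fmm = ll_at(theta - ei - ej)
                if all(map(math.isfinite, (fpp, fpm, fmp, fmm))):
                    hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                        4 * steps[i] * steps[j]
                    )
    se = {name: float("nan") for name in names}
    if ok and np.all(np.isfinite(hess)):
        try:
            cov = np.linalg.pinv(-hess)
            diag = np.diag(cov)
            for name, v in zip(names, diag):
                se[name] = float(math.sqrt(v)) if v > 0 else float("nan")
        except np.linalg.LinAlgError:
            pass
    return se


# ---------------------------------------------------------------------------
# Model comparison, heritability, BLUP, selection
# ---------------------------------------------------------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion
    ``-2 ll + 2k + 2k(k+1)/(n-k-1)``; requires ``n > k + 1``."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n must exceed k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def default_structures(median_range: float = 10.0) -> list[SpatialStructure]:
    """The seven candidate structures with neutral initial parameters."""
    return [
        SpatialStructure("exponential", r=median_range),
        SpatialStructure("gaussian", r=median_range),
        SpatialStructure("spherical", r=median_range),
        SpatialStructure("linear", r=median_range),
        SpatialStructure("rational", r=median_range),
        SpatialStructure("ar1", rho=0.5),
        SpatialStructure("ar1xar1", rho_row=0.5, rho_col=0.5),
    ]


def compare_models(
    data: ModelData,
    A: RelationshipMatrix | None,
    grid: GridAssignment | None,
    specs: Sequence[SpatialModelSpec] | None = None,
    pedigree: Pedigree | None = None,
    optimizer_config: OptimizerConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit each candidate model and rank by AICc (ascending).

    Default model set: the seven spatial-only structures, the animal-only
    model, and animal + AR1xAR1. Per-model fit failures become rows flagged
    ``failed`` instead of aborting the comparison.
    """
    if specs is None:
        med = _median_distance(data)
        specs = [SpatialModelSpec(genetic=None, structure=s) for s in default_structures(med)]
        specs.append(SpatialModelSpec(genetic="animal", structure=None, label="animal"))
        specs.append(
            SpatialModelSpec(
                genetic="animal",
                structure=SpatialStructure("ar1xar1", rho_row=0.5, rho_col=0.5),
                label="animal+ar1xar1",
            )
        )
    if len(specs) < 1:
        raise ValueError("need at least one model spec")
    rows = []
    fits: dict[str, FitResult] = {}
    for spec in specs:
        try:
            result = fit(spec, data, A, grid, pedigree, optimizer_config)
        except Exception as exc:  # propagate as a flagged row
            rows.append(
                {
                    "model": spec.label,
                    "intercept": np.nan,
                    "k": np.nan,
                    "loglik": np.nan,
                    "AICc": np.nan,
                    "h2": np.nan,
                    "status": f"failed: {exc}",
                }
            )
            continue
        fits[spec.label] = result
        rows.append(
            {
                "model": spec.label,
                "intercept": result.beta,
                "k": result.k,
                "loglik": result.loglik,
                "AICc": result.aicc,
                "h2": result.h2 if result.h2 is not None else np.nan,
                "status": "ok",
            }
        )
    table = pd.DataFrame(rows).sort_values("AICc", na_position="last").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table, fits


def heritability_from_components(sigma2_a: float, sigma2_xi: float, sigma2_eta: float) -> float:
    """Narrow-sense heritability with the spatial variance in the
    denominator: ``h2 = s2a / (s2a + s2xi + s2eta)``."""
    total = sigma2_a + sigma2_xi + sigma2_eta
    if total <= 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return sigma2_a / total


def heritability(fit_result: FitResult) -> float:
    if fit_result.spec.genetic is None:
        raise ValueError("model has no genetic term; h2 undefined")
    p = fit_result.params
    return heritability_from_components(
        p.get("sigma2_a", 0.0), p.get("sigma2_xi", 0.0), p.get("sigma2_eta", 0.0)
    )


def blup(
    fit_result: FitResult,
    data: ModelData,
    A: RelationshipMatrix,
    grid: GridAssignment | None = None,
    pedigree: Pedigree | None = None,
) -> pd.DataFrame:
    """Predicted breeding values ``u_hat = s2a * A Z' V^-1 (y - X b)`` for
    every pedigree member, including non-phenotyped parents (their
    predictions flow through A). Values in phenotype units."""
    spec = fit_result.spec
    if spec.genetic != "animal":
        raise ValueError("blup() requires an animal-model fit")
    params = fit_result.params
    n = data.y.size
    g_obs = A.submatrix(data.ids)
    v = params.get("sigma2_eta", 0.0) * np.eye(n) + params["sigma2_a"] * g_obs
    if spec.structure is not None:
        v = v + params["sigma2_xi"] * _structure_matrix(spec, params, data, grid)
    cho, _ = _chol_with_jitter(v)
    resid = data.y - fit_result.beta
    vi_resid = linalg.cho_solve((cho, True), resid)
    obs_idx = [A.index(i) for i in data.ids]
    a_cross = A.matrix[:, obs_idx]  # all pedigree members x observed
    u_hat = params["sigma2_a"] * (a_cross @ vi_resid)
    phenotyped = set(data.ids)
    return pd.DataFrame(
        {
            "id": A.ids,
            "ebv": u_hat,
            "phenotyped": [i in phenotyped for i in A.ids],
        }
    )


def rank_selection(
    breeding_values: dict[str, float] | pd.Series,
    top_n: int,
    mode: str = "forward",
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Deterministic selection list: descending breeding value, ties broken
    by id (lexicographic). ``mode`` is a bookkeeping label ("forward" for
    offspring, "backward" for parents); pass ``ids`` to restrict the pool."""
    if mode not in ("forward", "backward"):
        raise ValueError("mode must be 'forward' or 'backward'")
    if isinstance(breeding_values, pd.Series):
        breeding_values = breeding_values.to_dict()
    pool = {k: v for k, v in breeding_values.items() if ids is None or k in set(ids)}
    if top_n > len(pool):
        raise ValueError(f"top_n={top_n} exceeds population size {len(pool)}")
    ordered = sorted(pool.items(), key=lambda kv: (-kv[1], kv[0]))
    out = pd.DataFrame(ordered[:top_n], columns=["id", "ebv"])
    out.insert(0, "rank", np.arange(1, top_n + 1))
    out["mode"] = mode
    return out
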