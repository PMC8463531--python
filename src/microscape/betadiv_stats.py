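"""Beta-diversity statistics and model selection for simulated communities.

Replicate communities from one parameter combination are matched into
disjoint random pairs and compared with the classic Morisita overlap
index

    C = 2 Σ x_i y_i / ((λ_x + λ_y) · X · Y),   λ_x = Σ x_i(x_i−1) / (X(X−1)),

whose complement d = 1 − C serves as a dissimilarity.  The unbiased λ
(not the Morisita–Horn simplification) is used, so C can exceed 1 and
d can be negative whenever within-community aggregation is lower than
between-community overlap — i.e. alpha diversity exceeds beta
diversity.

The effect of connectivity c, of the number of initially fixed
individuals x, and of their interaction on the index is assessed with
a gamma GLM with inverse link,

    y_ijk = g^{-1}(β0 + β1·c_i + β2·x_j + β3·c_i x_j + e_ijk),

fitted by IRLS.  The five candidate models (null, Con, Fix, Con+Fix,
Con+Fix+Con:Fix) are ranked by AICc with Akaike weights, and the best
model is compared with the complete one through a scaled deviance
test.  Log-likelihood conventions follow R's ``logLik.glm`` for the
gamma family: dispersion φ̂ = residual deviance / n, shape = 1/φ̂,
scale = μφ̂; the model parameter count includes the dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import SimulationResult

__all__ = [
    "PairSet",
    "GLMDesign",
    "GLMFit",
    "ModelRanking",
    "DevianceTest",
    "morisita_overlap",
    "morisita_dissimilarity",
    "pair_replicates",
    "fit_gamma_glm",
    "aicc",
    "akaike_weights",
    "rank_models",
    "deviance_test",
    "metastability_analysis",
    "CANDIDATE_MODELS",
]

CANDIDATE_MODELS: dict[str, tuple[str, ...]] = {
    "null": (),
    "Con": ("connectivity",),
    "Fix": ("n_fixed",),
    "Con + Fix": ("connectivity", "n_fixed"),
    "Con + Fix + Con:Fix": ("connectivity", "n_fixed", "connectivity:n_fixed"),
}


@dataclass(frozen=True)
class PairSet:
    """Disjoint replicate pairs within one parameter combination."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        used = [r for pair in self.pairs for r in pair]
        if len(set(used)) != len(used):
            raise ValueError("pairs are not disjoint: a replicate is reused")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class GLMDesign:
    """Response plus numeric covariates for one candidate model.

    ``terms`` may include main effects (column names of ``covariates``)
    and interactions written ``a:b``.  The design matrix always holds
    an intercept.
    """

    y: np.ndarray
    covariates: pd.DataFrame
    terms: tuple[str, ...] = ()
    name: str = "model"

    def matrix(self) -> np.ndarray:
        n = len(self.y)
        cols = [np.ones(n)]
        for term in self.terms:
            if ":" in term:
                a, b = term.split(":")
                cols.append(self.covariates[a].to_numpy() * self.covariates[b].to_numpy())
            else:
                cols.append(self.covariates[term].to_numpy(dtype=float))
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"design matrix for model {self.name!r} is rank deficient")
        return X


@dataclass(frozen=True)
class GLMFit:
    """Fitted gamma GLM with the conventions used for ranking."""

    name: str
    terms: tuple[str, ...]
    coefficients: np.ndarray
    fitted: np.ndarray
    deviance: float
    phi_deviance: float
    phi_pearson: float
    loglik: float
    k: int  # coefficients + 1 for dispersion
    n: int

    @property
    def n_coefficients(self) -> int:
        return self.k - 1


@dataclass(frozen=True)
class ModelRanking:
    """AICc table: one row per model, sorted ascending by AICc."""

    table: pd.DataFrame  # columns: model, df, logLik, AICc, delta, weight

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])


@dataclass(frozen=True)
class DevianceTest:
    deviance: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# Morisita
# ---------------------------------------------------------------------------


def _lambda(x: np.ndarray) -> float:
    X = x.sum()
    return float((x * (x - 1)).sum() / (X * (X - 1)))


def morisita_overlap(x, y) -> float:
    """Classic Morisita overlap C between two count vectors.

    C approaches 0 for completely different communities and can exceed
    1 when cross-community overlap beats within-community aggregation.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("count vectors must have the same length")
    for v, name in ((x, "x"), (y, "y")):
        if np.any(v < 0) or not np.issubdtype(v.dtype, np.integer):
            if np.any(v < 0) or np.any(v != np.floor(v)):
                raise ValueError(f"{name} must contain non-negative integers")
    if x.sum() < 2 or y.sum() < 2:
        raise ValueError("each community needs total abundance >= 2 (lambda undefined)")
    X, Y = float(x.sum()), float(y.sum())
    lam = _lambda(x.astype(np.int64)) + _lambda(y.astype(np.int64))
    if lam == 0:
        raise ValueError("both communities are perfectly even singleton mixtures; "
                         "Morisita overlap undefined (lambda_x + lambda_y = 0)")
    return float(2.0 * np.dot(x.astype(float), y.astype(float)) / (lam * X * Y))


def morisita_dissimilarity(x, y) -> float:
    """d = 1 − C; may be negative when C > 1."""
    return 1.0 - morisita_overlap(x, y)


def pair_replicates(replicate_ids, seed=None) -> PairSet:
    """Uniformly random perfect matching of an even id list."""
    ids = list(replicate_ids)
    if len(ids) % 2 != 0:
        raise ValueError(f"cannot pair an odd number of replicates ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    return PairSet(tuple((shuffled[i], shuffled[i + 1]) for i in range(0, len(ids), 2)))


# ---------------------------------------------------------------------------
# gamma GLM, AICc, ranking
# ---------------------------------------------------------------------------


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


def _irls_gamma_inverse(
    y: np.ndarray, X: np.ndarray, tol: float = 1e-8, maxiter: int = 50
) -> tuple[np.ndarray, list[float]]:
    """IRLS for the gamma family with inverse link (mu = 1/eta).

    Working weights are mu^2 and the working response is
    z = eta − (y − mu)·eta^2; convergence when the relative deviance
    change drops below ``tol``.  Step halving keeps eta positive.
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, 1.0 / y, rcond=None)
    if np.any(X @ beta <= 0):
        beta = np.zeros(p)
        beta[0] = 1.0 / float(np.mean(y))
    eta = X @ beta
    mu = 1.0 / eta
    dev = _gamma_deviance(y, mu)
    trace = [dev]
    for _ in range(maxiter):
        w = mu**2
        z = eta - (y - mu) * eta**2
        WX = X * w[:, None]
        beta_target = np.linalg.solve(X.T @ WX, WX.T @ z)
        step = 1.0
        for _ in range(30):
            candidate = beta + step * (beta_target - beta)
            eta_c = X @ candidate
            if np.all(eta_c > 0):
                break
            step *= 0.5
        else:
            raise RuntimeError(
                "IRLS step could not keep the linear predictor positive; "
                f"deviance trace: {trace}"
            )
        beta, eta, mu = candidate, eta_c, 1.0 / eta_c
        dev_new = _gamma_deviance(y, mu)
        trace.append(dev_new)
        if abs(dev_new - dev) < tol * (abs(dev) + 0.1):
            return beta, trace
        dev = dev_new
    raise RuntimeError(
        f"IRLS did not converge within {maxiter} iterations; deviance trace: {trace}"
    )


def fit_gamma_glm(design: GLMDesign) -> GLMFit:
    """Fit a gamma GLM with inverse link by IRLS."""
    y = np.asarray(design.y, dtype=float)
    if np.any(y <= 0):
        bad = int(np.argmax(y <= 0))
        raise ValueError(f"gamma GLM requires a strictly positive response; y[{bad}] = {y[bad]}")
    X = design.matrix()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    try:
        beta, _ = _irls_gamma_inverse(y, X)
    except RuntimeError as err:
        raise RuntimeError(f"model {design.name!r}: {err}") from None
    mu = 1.0 / (X @ beta)
    if np.any(mu <= 0):
        raise RuntimeError(f"model {design.name!r} produced non-positive fitted means")
    deviance = _gamma_deviance(y, mu)
    phi_dev = deviance / n
    phi_pearson = float(np.sum((y - mu) ** 2 / mu**2)) / (n - p)
    if deviance > 0:
        shape = 1.0 / phi_dev
        loglik = float(np.sum(stats.gamma.logpdf(y, a=shape, scale=mu * phi_dev)))
    else:  # perfect fit: the gamma density degenerates
        loglik = np.inf
    return GLMFit(
        name=design.name,
        terms=tuple(design.terms),
        coefficients=beta,
        fitted=mu,
        deviance=deviance,
        phi_deviance=phi_dev,
        phi_pearson=phi_pearson,
        loglik=loglik,
        k=p + 1,
        n=n,
    )


def aicc(loglik, k: int | None = None, n: int | None = None) -> float:
    """AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1).

    Accepts either a :class:`GLMFit` or explicit (loglik, k, n).
    """
    if isinstance(loglik, GLMFit):
        fit = loglik
        loglik, k, n = fit.loglik, fit.k, fit.n
    if k is None or n is None:
        raise ValueError("k and n are required when loglik is a scalar")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * float(loglik) + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(deltas) -> np.ndarray:
    """Akaike weights exp(−Δ/2) normalized to sum 1."""
    deltas = np.asarray(deltas, dtype=float)
    raw = np.exp(-deltas / 2.0)
    return raw / raw.sum()


def rank_models(fits: list[GLMFit]) -> ModelRanking:
    """AICc table with deltas and Akaike weights, best model first."""
    ns = {fit.n for fit in fits}
    if len(ns) > 1:
        raise ValueError(f"fits have mismatched sample sizes: {sorted(ns)}")
    rows = [
        {"model": fit.name, "df": fit.k, "logLik": fit.loglik, "AICc": aicc(fit)}
        for fit in fits
    ]
    table = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    table["delta"] = table["AICc"] - table["AICc"].iloc[0]
    table["weight"] = akaike_weights(table["delta"].to_numpy())
    return ModelRanking(table)


def deviance_test(nested: GLMFit, full: GLMFit) -> DevianceTest:
    """Scaled deviance test of a nested gamma GLM against a fuller one.

    Uses the Pearson dispersion of the full model; the reference is
    chi-square with df = difference in coefficient counts.
    """
    if not set(nested.terms) <= set(full.terms):
        raise ValueError(
            f"model {nested.name!r} is not nested in {full.name!r}: "
            f"{set(nested.terms) - set(full.terms)} not in the full model"
        )
    if nested.n != full.n:
        raise ValueError("models were fitted on different sample sizes")
    diff = nested.deviance - full.deviance
    df = full.n_coefficients - nested.n_coefficients
    if df == 0:
        return DevianceTest(deviance=diff, df=0, p_value=1.0)
    p = float(stats.chi2.sf(diff / full.phi_pearson, df))
    return DevianceTest(deviance=diff, df=df, p_value=p)


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------


def pairwise_morisita_table(
    results: list[SimulationResult], seed: int = 0
) -> pd.DataFrame:
    """Pair replicates within each parameter combination and score pairs.

    Returns one row per pair: connectivity, n_fixed, the replicate ids,
    Morisita overlap C and dissimilarity d.  Pairs involving a
    community with total abundance < 2 (extinct or near-extinct) are
    dropped with a warning.
    """
    by_combo: dict[tuple[float, int], list[SimulationResult]] = {}
    for r in results:
        by_combo.setdefault((r.connectivity, r.n_fixed), []).append(r)
    root = np.random.SeedSequence(seed)
    combo_keys = sorted(by_combo)
    rows = []
    dropped = 0
    for combo_seq, key in zip(root.spawn(len(combo_keys)), combo_keys):
        conn, n_fixed = key
        reps = sorted(by_combo[key], key=lambda r: r.replicate)
        pairs = pair_replicates([r.replicate for r in reps], seed=combo_seq)
        by_id = {r.replicate: r for r in reps}
        for a, b in pairs.pairs:
            xa, xb = by_id[a].abundances, by_id[b].abundances
            if xa.sum() < 2 or xb.sum() < 2:
                dropped += 1
                continue
            C = morisita_overlap(xa, xb)
            rows.append(
                {
                    "connectivity": conn,
                    "n_fixed": n_fixed,
                    "replicate_a": a,
                    "replicate_b": b,
                    "C": C,
                    "d": 1.0 - C,
                }
            )
    if dropped:
        warnings.warn(f"dropped {dropped} pair(s) with total abundance < 2", stacklevel=2)
    return pd.DataFrame(rows)


def _choose_response(pairs: pd.DataFrame, response: str) -> tuple[np.ndarray, str]:
    d = pairs["d"].to_numpy()
    C = pairs["C"].to_numpy()
    if response == "neg-dissimilarity":
        if np.any(d >= 0):
            raise ValueError("response 'neg-dissimilarity' requires all dissimilarities < 0")
        return -d, "neg-dissimilarity"
    if response == "overlap":
        if np.any(C <= 0):
            raise ValueError("response 'overlap' requires all overlaps > 0")
        return C, "overlap"
    if response == "auto":
        if np.all(d < 0):
            return -d, "neg-dissimilarity"
        if np.all(d > 0):
            return d, "dissimilarity"
        if np.all(C > 0):
            return C, "overlap"
        raise ValueError("no strictly positive response transform available")
    raise ValueError(f"unknown response {response!r}")


def metastability_analysis(
    results: list[SimulationResult],
    seed: int = 0,
    response: str = "auto",
) -> tuple[pd.DataFrame, ModelRanking, DevianceTest, str]:
    """The full pairing → Morisita → GLM ranking → deviance-test study.

    Fits the five candidate models with numeric covariates, ranks them
    by AICc, and tests the best model against the complete one.
    Returns (per-pair table with the response column, ranking, test,
    response kind actually used).
    """
    pairs = pairwise_morisita_table(results, seed=seed)
    if pairs.empty:
        raise ValueError("no scorable pairs")
    y, kind = _choose_response(pairs, response)
    pairs = pairs.assign(response=y)
    covariates = pairs[["connectivity", "n_fixed"]].astype(float)
    fits = [
        fit_gamma_glm(GLMDesign(y=y, covariates=covariates, terms=terms, name=name))
        for name, terms in CANDIDATE_MODELS.items()
    ]
    ranking = rank_models(fits)
    by_name = {f.name: f for f in fits}
    best = by_name[ranking.best]
    full = by_name["Con + Fix + Con:Fix"]
    test = deviance_test(best, full)
    return pairs, ranking, test, kind
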