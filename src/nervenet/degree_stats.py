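"""Degree/multiplicity/terminal statistics and distribution-tail fitting.

Tail fitting follows the maximum-likelihood + Kolmogorov–Smirnov procedure:
for each candidate fit-start value the family parameter is fit by discrete
maximum likelihood, the start minimizing the KS distance is selected, and a
semiparametric bootstrap yields a goodness-of-fit p-value (plausibility
threshold 0.1).  Supported families: discrete power law (Hurwitz-zeta
normalization), discrete exponential (geometric tail), and the discrete
stretched exponential applied to the whole distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import zeta as hurwitz_zeta

from .wiring import AdjacencyNetwork

__all__ = [
    "DegreeSummary",
    "TailFit",
    "degree_summary",
    "survival_function",
    "fit_tail",
    "gof_pvalue",
    "fit_stretched_exponential",
    "compare_fits",
    "sequence_correlation",
]


class DegenerateDataError(ValueError):
    """All (tail) values identical: the MLE is unidentifiable."""


@dataclass
class DegreeSummary:
    names: list[str]
    degree: np.ndarray            # undirected connection count (on A or A|A^T)
    strength: np.ndarray          # number of terminals (summed multiplicities)
    multiplicities: np.ndarray    # per-connection contact counts
    in_degree: np.ndarray | None = None
    out_degree: np.ndarray | None = None
    in_number: np.ndarray | None = None
    out_number: np.ndarray | None = None

    @property
    def mean_multiplicity(self) -> float:
        return float(self.multiplicities.mean()) if len(self.multiplicities) else 0.0


@dataclass
class TailFit:
    family: str                   # power_law | exponential | stretched_exponential
    params: dict[str, float]
    xmin: int
    ks: float
    loglik: float
    n_tail: int
    min_tail: int = 10
    gof_pvalue: float | None = None

    def model_survival(self, ks_values: np.ndarray) -> np.ndarray:
        return _model_survival(self.family, self.params, self.xmin, ks_values)


def degree_summary(net: AdjacencyNetwork) -> DegreeSummary:
    """Binary statistics on A > 0; strength statistics on raw weights."""
    W = net.weights
    B = net.binary()
    if net.directed:
        Bu = np.maximum(B, B.T)
        iu, ju = np.nonzero(W)
        return DegreeSummary(
            names=list(net.names),
            degree=Bu.sum(axis=1).astype(int),
            strength=(W.sum(axis=1) + W.sum(axis=0)),
            multiplicities=W[iu, ju],
            in_degree=B.sum(axis=0).astype(int),
            out_degree=B.sum(axis=1).astype(int),
            in_number=W.sum(axis=0),
            out_number=W.sum(axis=1),
        )
    iu, ju = np.nonzero(np.triu(W))
    return DegreeSummary(
        names=list(net.names),
        degree=B.sum(axis=1).astype(int),
        strength=W.sum(axis=1),
        multiplicities=W[iu, ju],
    )


def survival_function(values) -> tuple[np.ndarray, np.ndarray]:
    """Survival table (k, F(k) = P(X >= k)) for k = min(values)..max(values)+1."""
    x = np.asarray(values)
    if x.size == 0:
        raise ValueError("survival_function requires non-empty input")
    ks = np.arange(int(x.min()), int(x.max()) + 2)
    F = np.array([(x >= k).mean() for k in ks])
    return ks, F


def survival_at(values, k: float) -> float:
    x = np.asarray(values)
    return float((x >= k).mean())


# ---------------------------------------------------------------------------
# Discrete families

_ZMAX = 200_000  # support cap for sampling/normalization of discrete models


def _model_survival(family: str, params: dict, xmin: int, ks_values: np.ndarray) -> np.ndarray:
    k = np.asarray(ks_values, dtype=float)
    if family == "power_law":
        alpha = params["alpha"]
        return hurwitz_zeta(alpha, np.maximum(k, xmin)) / hurwitz_zeta(alpha, xmin)
    if family == "exponential":
        rate = params["rate"]
        return np.exp(-rate * (np.maximum(k, xmin) - xmin))
    if family == "stretched_exponential":
        lam, beta = params["scale"], params["shape"]
        km = np.maximum(k, 1)
        return np.exp(-(((km - 1) / lam) ** beta))
    raise ValueError(f"unknown family {family!r}")


def _powerlaw_loglik(alpha: float, tail: np.ndarray, xmin: int) -> float:
    return float(-alpha * np.log(tail).sum() - len(tail) * np.log(hurwitz_zeta(alpha, xmin)))


def _fit_powerlaw_alpha(tail: np.ndarray, xmin: int) -> tuple[float, float]:
    slog = float(np.log(tail).sum())
    n = len(tail)
    res = optimize.minimize_scalar(
        lambda a: a * slog + n * np.log(hurwitz_zeta(a, xmin)),
        bounds=(1.000001, 12.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), -float(res.fun)


def _fit_exponential_rate(tail: np.ndarray, xmin: int) -> tuple[float, float]:
    """Discrete exponential P(x) = (1 - e^-r) e^{-r (x - xmin)}, x >= xmin.

    Closed-form MLE: e^-r = m / (m + 1) with m the mean excess."""
    m = float(tail.mean() - xmin)
    if m <= 0:
        raise DegenerateDataError("zero mean excess: exponential MLE degenerate")
    q = m / (m + 1)
    rate = -np.log(q)
    n = len(tail)
    loglik = n * np.log(1 - q) + np.log(q) * (tail - xmin).sum()
    return float(rate), float(loglik)


def _ks_statistic(tail: np.ndarray, family: str, params: dict, xmin: int) -> float:
    ks_grid = np.arange(xmin, tail.max() + 2)
    srt = np.sort(tail)
    emp = 1.0 - np.searchsorted(srt, ks_grid, side="left") / len(srt)
    model = _model_survival(family, params, xmin, ks_grid)
    return float(np.abs(emp - model).max())


def fit_tail(
    values, family: str = "power_law", min_tail: int = 10, max_candidates: int = 50
) -> TailFit:
    """Fit a tail family with xmin selected by minimal KS distance.

    For each candidate xmin (each distinct value leaving at least ``min_tail``
    distinct tail values), the family parameter is fit by discrete maximum
    likelihood on values >= xmin and the KS distance between the fitted and
    empirical tail survival recorded; the minimizing xmin wins.
    """
    x = np.asarray(values, dtype=int)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("no positive values to fit")
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise DegenerateDataError("all values identical: tail fit degenerate")
    candidates = [
        xm for xm in distinct if len(np.unique(x[x >= xm])) >= max(min_tail, 2)
    ]
    if not candidates:
        candidates = [int(distinct[0])]
    if len(candidates) > max_candidates:
        pick = np.unique(np.linspace(0, len(candidates) - 1, max_candidates).astype(int))
        candidates = [candidates[i] for i in pick]
    best: TailFit | None = None
    for xmin in candidates:
        tail = x[x >= xmin]
        if len(np.unique(tail)) < 2:
            continue
        try:
            if family == "power_law":
                alpha, loglik = _fit_powerlaw_alpha(tail, int(xmin))
                params = {"alpha": alpha}
            elif family == "exponential":
                rate, loglik = _fit_exponential_rate(tail, int(xmin))
                params = {"rate": rate}
            else:
                raise ValueError(f"fit_tail supports power_law/exponential, got {family!r}")
        except DegenerateDataError:
            continue
        ks = _ks_statistic(tail, family, params, int(xmin))
        fit = TailFit(family, params, int(xmin), ks, loglik, n_tail=len(tail), min_tail=min_tail)
        if best is None or fit.ks < best.ks:
            best = fit
    if best is None:
        raise DegenerateDataError("no admissible fit-start value")
    return best


def _tail_sampler(family: str, params: dict, xmin: int):
    """Inverse-CDF sampler for the fitted discrete tail model."""
    ks = np.arange(xmin, _ZMAX)
    surv = _model_survival(family, params, xmin, ks)
    pmf = surv - np.append(surv[1:], 0.0)
    pmf = np.clip(pmf, 0, None)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]

    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return ks[np.searchsorted(cdf, rng.random(size), side="left")]

    return draw


def gof_pvalue(fit: TailFit, values, n_boot: int = 1000, seed: int = 0) -> float:
    """Semiparametric bootstrap goodness-of-fit p-value.

    Each replicate resamples the body (values below xmin) with replacement
    and draws the tail from the fitted model, refits the same family with
    free xmin, and records its KS statistic; p is the fraction of replicate
    KS values >= the observed one.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = np.asarray(values, dtype=int)
    x = x[x > 0]
    rng = np.random.default_rng(seed)
    body = x[x < fit.xmin]
    n_tail = int((x >= fit.xmin).sum())
    p_tail = n_tail / len(x)
    draw = _tail_sampler(fit.family, fit.params, fit.xmin)
    n_extreme = 0
    for _ in range(n_boot):
        take_tail = rng.random(len(x)) < p_tail
        n_t = int(take_tail.sum())
        rep = np.concatenate(
            [
                draw(rng, n_t),
                rng.choice(body, size=len(x) - n_t, replace=True) if len(body) else
                draw(rng, len(x) - n_t),
            ]
        )
        try:
            rep_fit = fit_tail(rep, fit.family, min_tail=fit.min_tail, max_candidates=12)
        except DegenerateDataError:
            n_extreme += 1  # conservatively counted as extreme
            continue
        if rep_fit.ks >= fit.ks:
            n_extreme += 1
    return (1 + n_extreme) / (n_boot + 1)


def _stretched_loglik(theta: np.ndarray, x: np.ndarray) -> float:
    lam, beta = np.exp(theta)
    s_lo = np.exp(-(((x - 1) / lam) ** beta))
    s_hi = np.exp(-((x / lam) ** beta))
    pmf = np.clip(s_lo - s_hi, 1e-300, None)
    return float(np.log(pmf).sum())


def fit_stretched_exponential(values) -> TailFit:
    """MLE of the discrete stretched-exponential (Weibull) law
    P(M >= m) = exp(-((m-1)/scale)^shape), fit to the whole distribution."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 1):
        raise ValueError("stretched-exponential fit requires values >= 1")
    if len(np.unique(x)) < 2:
        raise DegenerateDataError("constant data: shape parameter unidentifiable")
    res = optimize.minimize(
        lambda th: -_stretched_loglik(th, x),
        x0=np.log([max(x.mean() - 1, 0.5), 1.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    lam, beta = np.exp(res.x)
    params = {"scale": float(lam), "shape": float(beta)}
    ks = _ks_statistic(x.astype(int), "stretched_exponential", params, 1)
    return TailFit(
        "stretched_exponential", params, 1, ks, -float(res.fun), n_tail=len(x), min_tail=1
    )


def compare_fits(fit_a: TailFit, fit_b: TailFit, values) -> tuple[str, float]:
    """Log-likelihood comparison on a common support.

    Both families are re-evaluated on the tail starting at the larger of the
    two selected xmin values, so the log-likelihoods are commensurable.
    Returns (preferred family, loglik_a - loglik_b).
    """
    x = np.asarray(values, dtype=int)
    x = x[x > 0]
    xmin = max(fit_a.xmin, fit_b.xmin)
    tail = x[x >= xmin]
    if len(np.unique(tail)) < 2:
        raise DegenerateDataError("common tail degenerate")

    def loglik_on(fit: TailFit) -> float:
        if fit.family == "power_law":
            return _fit_powerlaw_alpha(tail, xmin)[1]
        if fit.family == "exponential":
            return _fit_exponential_rate(tail, xmin)[1]
        if fit.family == "stretched_exponential":
            # whole-distribution fit: evaluated on its own support by design
            return fit.loglik if xmin == 1 else _stretched_loglik(
                np.log([fit.params["scale"], fit.params["shape"]]), tail
            )
        raise ValueError(fit.family)

    la, lb = loglik_on(fit_a), loglik_on(fit_b)
    diff = la - lb
    return (fit_a.family if diff >= 0 else fit_b.family), float(diff)


def sequence_correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Product-moment or rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("sequences must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance sequence")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
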