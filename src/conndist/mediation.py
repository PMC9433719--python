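"""Three-variable mediation with covariates and a bootstrap indirect effect.

Tests whether a mediator M explains the association of X with Y via the
classic two-equation linear system (covariates Z in every equation):

    M = i1 + a X + Z g1 + e1
    Y = i2 + c' X + b M + Z g2 + e2        (direct effect c', path b)
    Y = i3 + c X + Z g3 + e3               (total effect c)

X, M and Y are standardized to unit variance before fitting (covariates
left raw), so a, b, c, c' are standardized regression coefficients and the
indirect effect is a*b (= c - c', an exact OLS identity when the same
covariates enter all equations).  Significance of the indirect effect uses
a nonparametric subject-level bootstrap (resampling with replacement,
refitting, percentile 95% interval by default): the effect is significant
when 0 lies outside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

_MAX_RESAMPLE_ROUNDS = 100


@dataclass
class MediationResult:
    """Point estimates and bootstrap CI of a mediation fit."""

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    significant: bool
    n_boot: int
    ci_method: str = "percentile"
    indirect_boot: np.ndarray = field(default=None, repr=False)


def _standardize(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    sd = v.std()
    if sd == 0:
        raise ValueError(f"{name} is constant")
    return (v - v.mean()) / sd


def _solve_batched(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients for a (B, n, p) design stack against (B, n) targets."""
    G = np.einsum("bni,bnj->bij", X, X)
    h = np.einsum("bni,bn->bi", X, y)
    return np.linalg.solve(G, h[..., None])[..., 0]


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    ci_method: str = "percentile",
) -> MediationResult:
    """Fit the mediation system and bootstrap the indirect effect a*b.

    ``ci_method`` is ``"percentile"`` (default) or ``"bc"`` (bias-
    corrected percentile).  Deterministic given ``seed``.  Bootstrap
    samples in which the resampled x, m or y is constant are redrawn
    (bounded retries).
    """
    if ci_method not in ("percentile", "bc"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    x = _standardize(x, "x")
    m = _standardize(m, "m")
    y = _standardize(y, "y")
    n = x.shape[0]
    if m.shape[0] != n or y.shape[0] != n:
        raise ValueError("x, m, y lengths differ")
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError("covariates do not match number of subjects")
    k = 0 if covariates is None else covariates.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > covariates + 3 subjects, got n={n}, covariates={k}")

    def designs(xv, mv, cov):
        ones = np.ones(xv.shape)
        if xv.ndim == 1:
            base = [np.ones(n), xv]
            covc = [] if cov is None else list(cov.T)
            X1 = np.column_stack(base + covc)              # m ~ x + cov
            X2 = np.column_stack(base + [mv] + covc)       # y ~ x + m + cov
            return X1, X2
        # batched: xv, mv are (B, n); cov is (B, n, k)
        parts1 = [ones, xv]
        parts2 = [ones, xv, mv]
        if cov is not None:
            covs = [cov[..., j] for j in range(cov.shape[-1])]
            parts1 += covs
            parts2 += covs
        return np.stack(parts1, axis=-1), np.stack(parts2, axis=-1)

    X1, X2 = designs(x, m, covariates)
    a = float(np.linalg.lstsq(X1, m, rcond=None)[0][1])
    coef2 = np.linalg.lstsq(X2, y, rcond=None)[0]
    c_prime, b = float(coef2[1]), float(coef2[2])
    c = float(np.linalg.lstsq(X1, y, rcond=None)[0][1])  # same design as X1
    indirect = a * b

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    boot = np.empty(n_boot)
    # chunk the batched bootstrap to bound memory on large cohorts
    chunk = max(1, int(2_000_000 / max(n, 1)))
    done = 0
    while done < n_boot:
        B = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(B, n))
        for _ in range(_MAX_RESAMPLE_ROUNDS):
            bad = (
                (x[idx].std(axis=1) == 0)
                | (m[idx].std(axis=1) == 0)
                | (y[idx].std(axis=1) == 0)
            )
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        else:
            raise ValueError("degenerate bootstrap samples persist after retries")
        xb, mb, yb = x[idx], m[idx], y[idx]
        covb = covariates[idx] if covariates is not None else None
        Xb1, Xb2 = designs(xb, mb, covb)
        a_b = _solve_batched(Xb1, mb)[:, 1]
        b_b = _solve_batched(Xb2, yb)[:, 2]
        boot[done : done + B] = a_b * b_b
        done += B

    if ci_method == "percentile":
        ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    else:  # bias-corrected percentile
        frac = np.clip(np.mean(boot < indirect), 1e-12, 1 - 1e-12)
        z0 = sps.norm.ppf(frac)
        zc = sps.norm.ppf([0.025, 0.975])
        qs = sps.norm.cdf(2 * z0 + zc) * 100
        ci_low, ci_high = np.percentile(boot, qs)

    return MediationResult(
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=indirect,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        significant=bool(ci_low > 0 or ci_high < 0),
        n_boot=n_boot,
        ci_method=ci_method,
        indirect_boot=boot,
    )


class Mediation:
    """Scikit-learn-style estimator interface to :func:`mediate`.

    ``fit(x, m, y, covariates=None)`` exposes the fitted paths as
    ``a_``, ``b_``, ``c_``, ``c_prime_``, ``indirect_``, ``ci_`` and
    ``significant_``.
    """

    def __init__(self, n_boot: int = 5000, ci_method: str = "percentile", random_state: int = 0):
        self.n_boot = n_boot
        self.ci_method = ci_method
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_boot": self.n_boot,
            "ci_method": self.ci_method,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, x, m, y, covariates=None):
        result = mediate(
            x, m, y, covariates,
            n_boot=self.n_boot, seed=self.random_state, ci_method=self.ci_method,
        )
        self.result_ = result
        self.a_ = result.a
        self.b_ = result.b
        self.c_ = result.c
        self.c_prime_ = result.c_prime
        self.indirect_ = result.indirect
        self.ci_ = (result.ci_low, result.ci_high)
        self.significant_ = result.significant
        return self
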