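"""Single-season, single-species occupancy models with imperfect detection.

The likelihood is the zero-inflated binomial mixture over the latent occupied
state, with logit links on both occupancy (psi) and detection (p):

    L_i = psi_i * prod_k p_ik^y_ik (1 - p_ik)^(1 - y_ik)
          + (1 - psi_i) * 1{no detections at site i}

with the product over *active* occasions only. Model selection follows the
detection-first workflow: pick the best detection structure by (Q)AICc with
constant occupancy, test occupancy covariates univariately against it, then
fit all additive combinations of the significant ones. Goodness of fit uses
a parametric-bootstrap Pearson chi-square on detection-history frequencies,
yielding the variance-inflation factor c-hat; when c-hat > 1 the ranking
switches to QAICc and standard errors are inflated by sqrt(c-hat).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._utils import expit, safe_vcov
from .detections import DetectionHistory


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccuModelSpec:
    """Covariate names entering the occupancy and detection linear predictors.

    Empty tuples mean intercept-only. Detection covariates may include names
    provided through ``occasion_covariates`` (site x occasion arrays, e.g.
    season).
    """

    psi_covariates: tuple[str, ...] = ()
    p_covariates: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        psi = "+".join(self.psi_covariates) or "."
        p = "+".join(self.p_covariates) or "."
        return f"psi({psi})p({p})"


def build_designs(history: DetectionHistory, spec: OccuModelSpec,
                  covariates: pd.DataFrame | None = None,
                  occasion_covariates: dict[str, np.ndarray] | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Intercept-first design matrices: psi (n, P) and p (n, K, Q)."""
    n, k = history.matrix.shape
    occ = occasion_covariates or {}

    def site_column(name: str) -> np.ndarray:
        if covariates is None or name not in covariates.columns:
            raise KeyError(f"covariate {name!r} not found in table")
        col = covariates.loc[list(history.station_ids), name]
        if col.dtype == object:
            levels = sorted(col.unique())
            if len(levels) > 2:
                raise ValueError(f"categorical covariate {name!r} must be binary")
            col = (col == levels[-1]).astype(float)
        return col.to_numpy(dtype=float)

    psi_x = np.ones((n, 1 + len(spec.psi_covariates)))
    for j, name in enumerate(spec.psi_covariates, start=1):
        psi_x[:, j] = site_column(name)

    p_x = np.ones((n, k, 1 + len(spec.p_covariates)))
    for j, name in enumerate(spec.p_covariates, start=1):
        if name in occ:
            arr = np.asarray(occ[name], dtype=float)
            if arr.shape != (n, k):
                raise ValueError(f"occasion covariate {name!r} must be (n_sites, n_occasions)")
            p_x[:, :, j] = arr
        else:
            p_x[:, :, j] = site_column(name)[:, None]
    return psi_x, p_x


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def occu_loglik(y: np.ndarray, active: np.ndarray, psi_x: np.ndarray,
                p_x: np.ndarray, beta: np.ndarray, alpha: np.ndarray) -> float:
    """Log-likelihood of the occupancy mixture; inactive occasions contribute
    nothing. Sites with zero active occasions are skipped with a warning."""
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if psi_x.shape[1] != beta.size or p_x.shape[2] != alpha.size:
        raise ValueError("design/parameter dimension mismatch")
    site_ll = _site_loglik(y, active, psi_x, p_x, beta, alpha)
    empty = ~active.any(axis=1)
    if empty.any():
        warnings.warn(f"{int(empty.sum())} site(s) with no active occasions skipped",
                      stacklevel=2)
    return float(site_ll[~empty].sum())


def _site_loglik(y, active, psi_x, p_x, beta, alpha) -> np.ndarray:
    psi = expit(psi_x @ beta)
    p = expit(p_x @ alpha)
    yy = np.where(active, np.nan_to_num(y), 0.0)
    with np.errstate(divide="ignore"):
        logp = np.where(active, np.log(np.clip(p, 1e-300, None)), 0.0)
        log1mp = np.where(active, np.log(np.clip(1.0 - p, 1e-300, None)), 0.0)
    cond = np.where(active, yy * logp + (1.0 - yy) * log1mp, 0.0).sum(axis=1)
    detected = (yy * active).any(axis=1)
    # log( psi*exp(cond) + (1-psi)*1{no detections} ), stably
    occupied_term = np.log(np.clip(psi, 1e-300, None)) + cond
    out = np.where(
        detected,
        occupied_term,
        np.logaddexp(occupied_term, np.log(np.clip(1.0 - psi, 1e-300, None))),
    )
    return out


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2K + 2K(K+1)/(n-K-1); n = number of sites."""
    if n <= k + 1:
        raise ValueError("AICc undefined: n must exceed K + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def qaicc(loglik: float, k: int, n: int, chat: float) -> float:
    """Quasi-AICc with the overdispersion estimate counted as one extra
    parameter (K' = K + 1)."""
    if chat <= 0:
        raise ValueError("chat must be positive")
    kp = k + 1
    if n <= kp + 1:
        raise ValueError("QAICc undefined: n must exceed K + 2")
    return -2.0 * loglik / chat + 2.0 * kp + 2.0 * kp * (kp + 1) / (n - kp - 1)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _optimizer_ok(res, gtol: float = 1e-4) -> bool:
    """Accept BFGS 'precision loss' exits when the gradient is genuinely
    small (numeric-gradient BFGS routinely stops that way at the optimum)."""
    if res.success:
        return True
    jac = getattr(res, "jac", None)
    return jac is not None and np.all(np.isfinite(jac)) and \
        float(np.max(np.abs(jac))) < gtol * max(1.0, abs(res.fun))


@dataclass
class OccuFit:
    spec: OccuModelSpec
    beta: np.ndarray
    alpha: np.ndarray
    loglik: float
    n_sites: int
    vcov: np.ndarray
    converged: bool
    psi_names: tuple[str, ...] = ()
    p_names: tuple[str, ...] = ()

    @property
    def n_params(self) -> int:
        return self.beta.size + self.alpha.size

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.n_params, self.n_sites)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, self.alpha])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def coefficients(self) -> pd.DataFrame:
        """Tidy coefficient table on the link scale."""
        names = [f"psi_{n}" for n in self.psi_names] + [f"p_{n}" for n in self.p_names]
        return pd.DataFrame({"term": names, "estimate": self.params, "se": self.se})

    def psi_hat(self, psi_x: np.ndarray | None = None) -> np.ndarray:
        x = psi_x if psi_x is not None else np.ones((1, self.beta.size))
        return expit(x @ self.beta)

    def p_hat(self, p_x: np.ndarray | None = None) -> np.ndarray:
        x = p_x if p_x is not None else np.ones((1, self.alpha.size))
        return expit(x @ self.alpha)


def fit_occu(history: DetectionHistory, covariates: pd.DataFrame | None = None,
             spec: OccuModelSpec | None = None,
             occasion_covariates: dict[str, np.ndarray] | None = None,
             n_restarts: int = 5, seed: int = 0, start: np.ndarray | None = None,
             compute_vcov: bool = True) -> OccuFit:
    """Maximum-likelihood fit by quasi-Newton (BFGS) from zero-initialised
    link-scale parameters, with jittered restarts on failure."""
    spec = spec or OccuModelSpec()
    y = history.matrix
    active = history.active
    if not np.nansum(y) >= 1:
        raise ValueError("species never detected; occupancy not estimable")
    psi_x, p_x = build_designs(history, spec, covariates, occasion_covariates)
    n_p, n_a = psi_x.shape[1], p_x.shape[2]
    keep = active.any(axis=1)
    y, active, psi_x, p_x = y[keep], active[keep], psi_x[keep], p_x[keep]

    def nll(theta: np.ndarray) -> float:
        val = _site_loglik(y, active, psi_x, p_x, theta[:n_p], theta[n_p:]).sum()
        return -val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    x0 = np.zeros(n_p + n_a) if start is None else np.asarray(start, dtype=float)
    best = None
    for attempt in range(n_restarts + 1):
        init = x0 if attempt == 0 else x0 + rng.normal(scale=0.5 * attempt, size=x0.size)
        res = minimize(nll, init, method="BFGS",
                       options={"gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if _optimizer_ok(best):
            break

    theta = best.x
    if compute_vcov:
        vcov, vcov_ok = safe_vcov(nll, theta)
    else:
        vcov, vcov_ok = np.full((theta.size, theta.size), np.nan), True
    return OccuFit(
        spec=spec,
        beta=theta[:n_p],
        alpha=theta[n_p:],
        loglik=-best.fun,
        n_sites=int(keep.sum()),
        vcov=vcov,
        converged=bool(_optimizer_ok(best) and vcov_ok),
        psi_names=("(intercept)",) + spec.psi_covariates,
        p_names=("(intercept)",) + spec.p_covariates,
    )


# ---------------------------------------------------------------------------
# goodness of fit (parametric-bootstrap Pearson chi-square, c-hat)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GofResult:
    chi2_obs: float
    p_value: float
    chat: float
    n_boot: int
    n_failed: int


def _history_prob(yh: np.ndarray, psi: np.ndarray, p: np.ndarray,
                  active_cols: np.ndarray) -> np.ndarray:
    """P(observed history yh | site) for every site in a cohort."""
    pa = p[:, active_cols]
    cond = np.prod(np.where(yh[None, :] == 1, pa, 1.0 - pa), axis=1)
    if yh.any():
        return psi * cond
    return psi * cond + (1.0 - psi)


def _pearson_chi2(y: np.ndarray, active: np.ndarray, psi: np.ndarray,
                  p: np.ndarray) -> float:
    """Chi-square over detection-history frequencies.

    Sites are grouped into cohorts by missing-occasion pattern. Within each
    cohort every distinct observed history is a cell with (O-E)^2/E; the
    histories never observed contribute their total expectation
    N_cohort - sum(E_observed) (their observed count is zero), which avoids
    enumerating all 2^K possible histories.
    """
    chi2 = 0.0
    patterns = {}
    for i in range(y.shape[0]):
        patterns.setdefault(tuple(active[i]), []).append(i)
    for pattern, idx in patterns.items():
        cols = np.flatnonzero(np.asarray(pattern))
        if cols.size == 0:
            continue
        idx = np.asarray(idx)
        sub = np.nan_to_num(y[idx][:, cols]).astype(int)
        uniq, counts = np.unique(sub, axis=0, return_counts=True)
        expected = np.array([
            _history_prob(h, psi[idx], p[idx], cols).sum() for h in uniq
        ])
        expected = np.clip(expected, 1e-12, None)
        chi2 += float(((counts - expected) ** 2 / expected).sum())
        chi2 += max(len(idx) - expected.sum(), 0.0)
    return chi2


def mb_gof(fit: OccuFit, history: DetectionHistory,
           covariates: pd.DataFrame | None = None,
           occasion_covariates: dict[str, np.ndarray] | None = None,
           n_boot: int = 1000, seed: int = 0) -> GofResult:
    """Parametric-bootstrap goodness of fit on detection-history frequencies.

    c-hat = chi2_obs / mean(chi2_boot); p = Pr(chi2_boot >= chi2_obs).
    Bootstrap refits that fail to converge are dropped and counted.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable c-hat", stacklevel=2)
    rng = np.random.default_rng(seed)
    psi_x, p_x = build_designs(history, fit.spec, covariates, occasion_covariates)
    keep = history.active.any(axis=1)
    y, active = history.matrix[keep], history.active[keep]
    psi_x, p_x = psi_x[keep], p_x[keep]
    psi = expit(psi_x @ fit.beta)
    p = expit(p_x @ fit.alpha)

    chi2_obs = _pearson_chi2(y, active, psi, p)

    boots = []
    n_failed = 0
    n, k = y.shape
    for _ in range(n_boot):
        z = rng.random(n) < psi
        sim = np.where(active, (rng.random((n, k)) < p) & z[:, None], np.nan)
        sim = sim.astype(float)
        sim[~active] = np.nan
        if np.nansum(sim) < 1:
            n_failed += 1
            continue
        sim_hist = DetectionHistory(history.species, tuple(np.array(history.station_ids)[keep]),
                                    history.occasion_length, sim)
        try:
            refit = fit_occu(sim_hist, covariates, fit.spec, occasion_covariates,
                             n_restarts=1, seed=int(rng.integers(2**31)),
                             start=fit.params, compute_vcov=False)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        b_psi_x, b_p_x = psi_x, p_x
        b_psi = expit(b_psi_x @ refit.beta)
        b_p = expit(b_p_x @ refit.alpha)
        boots.append(_pearson_chi2(sim, active, b_psi, b_p))

    boots = np.asarray(boots)
    if boots.size == 0:
        raise RuntimeError("all bootstrap replicates failed")
    chat = chi2_obs / float(boots.mean())
    p_value = float((boots >= chi2_obs).mean())
    return GofResult(chi2_obs=float(chi2_obs), p_value=p_value, chat=float(chat),
                     n_boot=int(boots.size), n_failed=n_failed)


# ---------------------------------------------------------------------------
# ranking and model averaging
# ---------------------------------------------------------------------------

@dataclass
class ModelSet:
    """Fits ranked by (Q)AICc with Akaike weights and averaged coefficients."""

    fits: list[OccuFit]
    criterion: str
    chat: float
    values: np.ndarray
    deltas: np.ndarray
    weights: np.ndarray
    delta_max: float
    averaged: pd.DataFrame = field(default_factory=pd.DataFrame)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": [f.spec.label for f in self.fits],
            "K": [f.n_params for f in self.fits],
            "loglik": [f.loglik for f in self.fits],
            self.criterion: self.values,
            "delta": self.deltas,
            "weight": self.weights,
        })


def rank_and_average(fits: list[OccuFit], chat: float = 1.0,
                     delta_max: float = 6.0) -> ModelSet:
    """Rank converged fits and average coefficients over the Delta < delta_max set.

    Uses AICc when chat <= 1, otherwise QAICc with standard errors inflated
    by sqrt(chat). Averaging is conditional (per-covariate, over the models
    containing it); unconditional SEs combine within-model variance and
    between-model spread.
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to rank")
    use_q = chat > 1.0
    criterion = "QAICc" if use_q else "AICc"
    values = np.array([
        qaicc(f.loglik, f.n_params, f.n_sites, chat) if use_q else f.aicc
        for f in fits
    ])
    order = np.argsort(values)
    fits = [fits[i] for i in order]
    values = values[order]
    deltas = values - values[0]
    in_set = deltas < delta_max
    weights = np.where(in_set, np.exp(-deltas / 2.0), 0.0)
    weights = weights / weights.sum()

    se_scale = np.sqrt(chat) if use_q else 1.0
    terms: dict[str, list[tuple[float, float, float]]] = {}
    for f, w in zip(fits, weights):
        if w == 0.0:
            continue
        coef = f.coefficients()
        for term, est, se in zip(coef["term"], coef["estimate"], coef["se"]):
            terms.setdefault(term, []).append((w, est, se * se_scale))
    rows = []
    for term, entries in terms.items():
        w = np.array([e[0] for e in entries])
        est = np.array([e[1] for e in entries])
        se = np.array([e[2] for e in entries])
        w = w / w.sum()
        avg = float((w * est).sum())
        # Burnham & Anderson unconditional SE
        use = float(np.sqrt((w * (se**2 + (est - avg) ** 2)).sum()))
        rows.append({"term": term, "estimate": avg, "se": use,
                     "lcl": avg - 1.96 * use, "ucl": avg + 1.96 * use})
    averaged = pd.DataFrame(rows)
    return ModelSet(fits=fits, criterion=criterion, chat=chat, values=values,
                    deltas=deltas, weights=weights, delta_max=delta_max,
                    averaged=averaged)


# ---------------------------------------------------------------------------
# detection-first selection workflow
# ---------------------------------------------------------------------------

def selection_workflow(history: DetectionHistory, covariates: pd.DataFrame,
                       detection_candidates: list[str],
                       occupancy_candidates: list[str],
                       occasion_covariates: dict[str, np.ndarray] | None = None,
                       chat: float | None = None, n_boot: int = 0, seed: int = 0,
                       delta_max: float = 6.0, max_combo: int | None = None,
                       ) -> ModelSet:
    """Three-stage model selection ending in a ranked, averaged ModelSet.

    Stage 1 picks the best detection structure (all single detection
    candidates plus the null) under constant occupancy. Stage 2 tests each
    occupancy covariate univariately with the stage-1 detection model. Stage 3
    fits every additive combination of stage-2 covariates whose Wald 95%
    interval excludes zero. When ``chat`` is None and ``n_boot`` > 0, c-hat is
    estimated on the global model via :func:`mb_gof`; otherwise 1 is assumed.
    """
    def fit(spec: OccuModelSpec) -> OccuFit:
        return fit_occu(history, covariates, spec, occasion_covariates, seed=seed)

    # stage 1: detection structure
    p_specs = [OccuModelSpec((), ())] + [
        OccuModelSpec((), (c,)) for c in detection_candidates
    ]
    if len(detection_candidates) > 1:
        p_specs.append(OccuModelSpec((), tuple(detection_candidates)))
    stage1 = [fit(s) for s in p_specs]
    best_p = min((f for f in stage1 if f.converged), key=lambda f: f.aicc).spec.p_covariates

    # stage 2: univariate occupancy covariates
    null_fit = fit(OccuModelSpec((), best_p))
    stage2 = {c: fit(OccuModelSpec((c,), best_p)) for c in occupancy_candidates}

    significant = []
    for c, f in stage2.items():
        if not f.converged:
            continue
        coef = f.coefficients()
        row = coef.loc[coef["term"] == f"psi_{c}"].iloc[0]
        if abs(row["estimate"]) > 1.96 * row["se"]:
            significant.append(c)

    # stage 3: additive combinations of significant covariates
    stage3 = []
    top = len(significant) if max_combo is None else min(max_combo, len(significant))
    for r in range(2, top + 1):
        for combo in itertools.combinations(significant, r):
            stage3.append(fit(OccuModelSpec(tuple(combo), best_p)))

    all_fits = [null_fit] + list(stage2.values()) + stage3

    if chat is None:
        if n_boot > 0:
            global_spec = OccuModelSpec(tuple(occupancy_candidates), best_p)
            global_fit = fit(global_spec)
            chat = mb_gof(global_fit, history, covariates, occasion_covariates,
                          n_boot=n_boot, seed=seed).chat
        else:
            chat = 1.0

    return rank_and_average(all_fits, chat=chat, delta_max=delta_max)
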