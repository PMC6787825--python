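"""Conditional two-species occupancy models and species interaction factors.

Species A is the dominant species, species B the subordinate. The model
carries eight probabilities:

==========  =====================================================
psiA        occupancy of A
psiBA       occupancy of B given A present
psiBa       occupancy of B given A absent
pA          detection of A given B absent
pB          detection of B given A absent
rA          detection of A when both present
rBA         detection of B when both present, on occasions A was detected
rBa         detection of B when both present, on occasions A was not detected
==========  =====================================================

Each is an intercept (optionally plus covariates) on the logit scale.
Constrained submodels tie parameters exactly by sharing coefficient groups.
The species interaction factors are ratios of joint probability to the
product of marginals: values below 1 indicate avoidance, above 1 attraction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._utils import expit, numeric_gradient, safe_vcov
from .detections import DetectionHistory

PARAM_NAMES = ("psiA", "psiBA", "psiBa", "pA", "pB", "rA", "rBA", "rBa")

#: Named tie structures. Each maps a parameter to the coefficient group it
#: shares; unmapped parameters get their own group.
CONSTRAINT_SETS: dict[str, dict[str, str]] = {
    # B ignores A entirely: psiBA = psiBa, pB = rBA = rBa
    "independent": {"psiBA": "psiB", "psiBa": "psiB",
                    "pB": "rB", "rBA": "rB", "rBa": "rB"},
    # presence of A shifts occupancy of B only
    "occupancy": {"pB": "rB", "rBA": "rB", "rBa": "rB"},
    # presence of A shifts detection of B (pB != rBA = rBa)
    "detection_presence": {"psiBA": "psiB", "psiBa": "psiB",
                           "rBA": "rBboth", "rBa": "rBboth"},
    # detection of A shifts detection of B (rBA != rBa, rBa tied to pB)
    "detection_detection": {"psiBA": "psiB", "psiBa": "psiB",
                            "pB": "rBbase", "rBa": "rBbase"},
    # occupancy and detection interactions both free
    "full": {},
}


def _check_histories(hist_a: DetectionHistory, hist_b: DetectionHistory) -> None:
    if hist_a.station_ids != hist_b.station_ids:
        raise ValueError("histories must share stations")
    if hist_a.matrix.shape != hist_b.matrix.shape:
        raise ValueError("histories must share occasions")
    if not np.array_equal(hist_a.active, hist_b.active):
        raise ValueError("histories must share missingness")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def two_species_loglik(hist_a: DetectionHistory, hist_b: DetectionHistory,
                       params: dict[str, float | np.ndarray]) -> float:
    """Mixture log-likelihood over the four latent occupancy states.

    ``params`` maps each name in :data:`PARAM_NAMES` to a probability
    (scalar or per-site array). States inconsistent with the observations
    contribute zero; inactive occasions contribute nothing.
    """
    _check_histories(hist_a, hist_b)
    missing = [k for k in PARAM_NAMES if k not in params]
    if missing:
        raise ValueError(f"missing parameters: {missing}")
    active = hist_a.active
    ya = np.nan_to_num(hist_a.matrix)
    yb = np.nan_to_num(hist_b.matrix)
    n, k = ya.shape

    def per_site(name: str) -> np.ndarray:
        return np.broadcast_to(np.asarray(params[name], dtype=float), (n,))

    psiA, psiBA, psiBa = per_site("psiA"), per_site("psiBA"), per_site("psiBa")
    pA, pB = per_site("pA"), per_site("pB")
    rA, rBA, rBa = per_site("rA"), per_site("rBA"), per_site("rBa")

    def occ_prod(prob: np.ndarray, y: np.ndarray) -> np.ndarray:
        """prod over active occasions of prob^y (1-prob)^(1-y), per site."""
        p = prob[:, None]
        f = np.where(active, np.where(y == 1, p, 1.0 - p), 1.0)
        return f.prod(axis=1)

    a_detected = (ya * active).any(axis=1)
    b_detected = (yb * active).any(axis=1)

    # state (A=1, B=1): A detected with rA; B with rBA/rBa per A's detections
    f_a11 = occ_prod(rA, ya)
    pb_both = np.where(ya == 1, rBA[:, None], rBa[:, None])
    f_b11 = np.where(active, np.where(yb == 1, pb_both, 1.0 - pb_both), 1.0).prod(axis=1)
    l11 = psiA * psiBA * f_a11 * f_b11
    # state (A=1, B=0): only consistent when B never detected
    l10 = psiA * (1.0 - psiBA) * occ_prod(pA, ya) * (~b_detected)
    # state (A=0, B=1)
    l01 = (1.0 - psiA) * psiBa * occ_prod(pB, yb) * (~a_detected)
    # state (A=0, B=0)
    l00 = (1.0 - psiA) * (1.0 - psiBa) * (~a_detected) * (~b_detected)

    site_l = l11 + l10 + l01 + l00
    keep = active.any(axis=1)
    return float(np.log(np.clip(site_l[keep], 1e-300, None)).sum())


# ---------------------------------------------------------------------------
# fitting with tie constraints
# ---------------------------------------------------------------------------

@dataclass
class TwoSpeciesFit:
    """ML fit of one constrained two-species model (intercepts + optional
    site covariates per parameter)."""

    constraint: str
    ties: dict[str, str]
    group_names: tuple[str, ...]
    group_designs: dict[str, np.ndarray]
    param_groups: dict[str, str]
    estimates: np.ndarray
    slices: dict[str, slice]
    vcov: np.ndarray
    loglik: float
    n_sites: int
    converged: bool

    @property
    def n_params(self) -> int:
        return self.estimates.size

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def param_values(self, at_mean: bool = True) -> dict[str, float]:
        """Probabilities at mean (zero, after standardisation) covariates."""
        out = {}
        for name in PARAM_NAMES:
            g = self.param_groups[name]
            coef = self.estimates[self.slices[g]]
            out[name] = float(expit(coef[0]))  # intercept-first designs
        return out

    def is_tied(self, a: str, b: str) -> bool:
        return self.param_groups[a] == self.param_groups[b]


def _resolve_groups(ties: dict[str, str]) -> dict[str, str]:
    return {name: ties.get(name, name) for name in PARAM_NAMES}


def fit_two_species_model(hist_a: DetectionHistory, hist_b: DetectionHistory,
                          ties: dict[str, str] | None = None,
                          constraint: str = "custom",
                          covariates: pd.DataFrame | None = None,
                          param_covariates: dict[str, tuple[str, ...]] | None = None,
                          n_restarts: int = 3, seed: int = 0) -> TwoSpeciesFit:
    """Fit one constrained model by BFGS on the link scale.

    ``param_covariates`` maps parameter names to site-covariate names added
    to that parameter's linear predictor; tied parameters must share the
    same covariate list.
    """
    _check_histories(hist_a, hist_b)
    ties = ties or {}
    param_groups = _resolve_groups(ties)
    groups = tuple(dict.fromkeys(param_groups.values()))
    n = hist_a.n_sites
    pc = param_covariates or {}

    group_designs: dict[str, np.ndarray] = {}
    for g in groups:
        members = [p for p in PARAM_NAMES if param_groups[p] == g]
        covs = {tuple(pc.get(m, ())) for m in members}
        if len(covs) > 1:
            raise ValueError(f"tied parameters {members} have differing covariates")
        names = covs.pop()
        x = np.ones((n, 1 + len(names)))
        for j, cname in enumerate(names, start=1):
            x[:, j] = covariates.loc[list(hist_a.station_ids), cname].to_numpy(float)
        group_designs[g] = x

    slices: dict[str, slice] = {}
    offset = 0
    for g in groups:
        width = group_designs[g].shape[1]
        slices[g] = slice(offset, offset + width)
        offset += width

    def unpack(theta: np.ndarray) -> dict[str, np.ndarray]:
        return {
            name: expit(group_designs[param_groups[name]] @ theta[slices[param_groups[name]]])
            for name in PARAM_NAMES
        }

    def nll(theta: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = two_species_loglik(hist_a, hist_b, unpack(theta))
        return -val if np.isfinite(val) else 1e12

    from .occupancy import _optimizer_ok

    rng = np.random.default_rng(seed)
    x0 = np.zeros(offset)
    best = None
    for attempt in range(n_restarts + 1):
        init = x0 if attempt == 0 else rng.normal(scale=0.5, size=offset)
        res = minimize(nll, init, method="BFGS", options={"gtol": 1e-8, "maxiter": 1000})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if _optimizer_ok(best):
            break

    vcov, vcov_ok = safe_vcov(nll, best.x)
    boundary = bool(np.any(np.abs(best.x) > 15))
    if boundary:
        warnings.warn("estimate at a boundary (|logit| > 15)", stacklevel=2)
    return TwoSpeciesFit(
        constraint=constraint, ties=dict(ties), group_names=groups,
        group_designs=group_designs, param_groups=param_groups,
        estimates=best.x, slices=slices, vcov=vcov, loglik=-best.fun,
        n_sites=n, converged=bool(_optimizer_ok(best) and vcov_ok),
    )


def fit_two_species(hist_a: DetectionHistory, hist_b: DetectionHistory,
                    constraint_set: str | list[str] = "all",
                    covariates: pd.DataFrame | None = None,
                    param_covariates: dict[str, tuple[str, ...]] | None = None,
                    seed: int = 0) -> list[TwoSpeciesFit]:
    """Fit the enumerated constraint set and rank by AIC (best first).

    When ``param_covariates`` is given, each structural model is fitted both
    with and without the covariates, mirroring the habitat-vs-interaction
    comparison.
    """
    names = list(CONSTRAINT_SETS) if constraint_set == "all" else list(constraint_set)
    fits: list[TwoSpeciesFit] = []
    for cname in names:
        ties = CONSTRAINT_SETS[cname]
        fits.append(fit_two_species_model(hist_a, hist_b, ties, cname,
                                          covariates, None, seed=seed))
        if param_covariates:
            fits.append(fit_two_species_model(
                hist_a, hist_b, ties, cname + "+covs", covariates,
                param_covariates, seed=seed))
    fits.sort(key=lambda f: f.aic if f.converged else np.inf)
    return fits


def model_table(fits: list[TwoSpeciesFit]) -> pd.DataFrame:
    aics = np.array([f.aic for f in fits])
    return pd.DataFrame({
        "model": [f.constraint for f in fits],
        "K": [f.n_params for f in fits],
        "loglik": [f.loglik for f in fits],
        "AIC": aics,
        "deltaAIC": aics - aics.min(),
        "converged": [f.converged for f in fits],
    })


# ---------------------------------------------------------------------------
# species interaction factors
# ---------------------------------------------------------------------------

def sif_occupancy(psi_a: float, psi_ba: float, psi_b_a: float) -> float:
    """Occupancy SIF: joint occupancy over the product of marginals.

    Phi = (psiA * psiBA) / (psiA * [psiA * psiBA + (1 - psiA) * psiBa]);
    equals 1 exactly when psiBA == psiBa.
    """
    denom = psi_a * (psi_a * psi_ba + (1.0 - psi_a) * psi_b_a)
    if denom == 0:
        raise ZeroDivisionError("SIF undefined: zero marginal occupancy")
    return (psi_a * psi_ba) / denom


def sif_detection(r_a: float, r_ba: float, r_b_a: float) -> float:
    """Detection SIF: delta = (rA*rBA) / (rA*[rA*rBA + (1-rA)*rBa])."""
    denom = r_a * (r_a * r_ba + (1.0 - r_a) * r_b_a)
    if denom == 0:
        raise ZeroDivisionError("SIF undefined: zero co-detection denominator")
    return (r_a * r_ba) / denom


@dataclass(frozen=True)
class SifResult:
    phi: float | None
    phi_se: float | None
    phi_ci: tuple[float, float] | None
    delta: float | None
    delta_se: float | None
    delta_ci: tuple[float, float] | None
    phi_interpretation: str | None
    delta_interpretation: str | None


def _interpret(value: float, ci: tuple[float, float]) -> str:
    lcl, ucl = ci
    if ucl < 1.0:
        return "avoidance"
    if lcl > 1.0:
        return "attraction"
    return "independent"


def sif_uncertainty(fit: TwoSpeciesFit) -> SifResult:
    """Delta-method SEs and Wald 95% CIs for both interaction factors.

    Tied parameters force the corresponding SIF to exactly 1 with SE 0.
    """
    vals = fit.param_values()

    def sif_with_se(kind: str) -> tuple[float, float]:
        if kind == "phi":
            tied = fit.is_tied("psiBA", "psiBa")
            func = lambda v: sif_occupancy(v["psiA"], v["psiBA"], v["psiBa"])
        else:
            tied = fit.is_tied("rBA", "rBa")
            func = lambda v: sif_detection(v["rA"], v["rBA"], v["rBa"])
        if tied:
            return 1.0, 0.0

        def of_theta(theta: np.ndarray) -> float:
            v = {
                name: float(expit(theta[fit.slices[fit.param_groups[name]]][0]))
                for name in PARAM_NAMES
            }
            return func(v)

        value = of_theta(fit.estimates)
        grad = numeric_gradient(of_theta, fit.estimates)
        var = float(grad @ fit.vcov @ grad)
        return value, float(np.sqrt(max(var, 0.0)))

    phi, phi_se = sif_with_se("phi")
    delta, delta_se = sif_with_se("delta")
    phi_ci = (phi - 1.96 * phi_se, phi + 1.96 * phi_se)
    delta_ci = (delta - 1.96 * delta_se, delta + 1.96 * delta_se)
    return SifResult(
        phi=phi, phi_se=phi_se, phi_ci=phi_ci,
        delta=delta, delta_se=delta_se, delta_ci=delta_ci,
        phi_interpretation=_interpret(phi, phi_ci),
        delta_interpretation=_interpret(delta, delta_ci),
    )
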