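"""Synthetic camera-trap surveys: stations, effort, covariates, detection
records and ground truth, for every pipeline stage.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded from
the scenario, so output is bit-reproducible across platforms.

Detections are generated at daily resolution and collapsed to occasions by
the IO layer; a per-occasion detection probability ``p`` converts to the
daily rate ``q = 1 - (1 - p)^(1/L)`` for occasion length ``L``. Two-species
conditional detection is applied at occasion granularity so the generative
process matches the estimator's assumptions exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from ._utils import expit
from .cooccurrence import sif_detection, sif_occupancy
from .detections import StationEffort

TWO_PI = 2.0 * np.pi

#: (mean angle, concentration, weight) triples; 24 h = 2 pi, 0 = midnight.
ActivityMixture = tuple[tuple[float, float, float], ...]


def _hour(h: float) -> float:
    return (h % 24.0) * TWO_PI / 24.0


#: Qualitative diel templates: a nocturnal unimodal pattern, a bimodal
#: nocturnal pattern with a mid-night lull, and a diurnal pattern.
NOCTURNAL: ActivityMixture = ((_hour(1.0), 2.0, 1.0),)
NOCTURNAL_BIMODAL: ActivityMixture = ((_hour(21.0), 4.0, 0.5), (_hour(4.5), 4.0, 0.5))
DIURNAL: ActivityMixture = ((_hour(13.0), 2.5, 1.0),)


@dataclass(frozen=True)
class SpeciesScenario:
    """Generating model for one species: logit-scale coefficient maps for
    occupancy and detection (key "(intercept)" plus covariate names) and a
    von Mises activity mixture."""

    name: str
    psi_coefs: dict[str, float]
    p_coefs: dict[str, float]
    activity: ActivityMixture = NOCTURNAL


@dataclass(frozen=True)
class TwoSpeciesBlock:
    """Interaction scenario: conditional occupancy/detection probabilities
    for a dominant species A and subordinate species B."""

    species_a: str
    species_b: str
    psiA: float = 0.55
    psiBA: float = 0.3
    psiBa: float = 0.7
    pA: float = 0.35
    pB: float = 0.35
    rA: float = 0.35
    rBA: float = 0.35
    rBa: float = 0.35
    activity_a: ActivityMixture = NOCTURNAL
    activity_b: ActivityMixture = NOCTURNAL_BIMODAL

    @property
    def true_phi(self) -> float:
        return sif_occupancy(self.psiA, self.psiBA, self.psiBa)

    @property
    def true_delta(self) -> float:
        return sif_detection(self.rA, self.rBA, self.rBa)


@dataclass(frozen=True)
class SimScenario:
    """Full survey scenario; defaults mirror a ~127-station survey with
    stations operational ~76.6 (SD 13.8) days and 6-day occasions."""

    n_stations: int = 127
    mean_days: float = 76.6
    sd_days: float = 13.8
    min_days: int = 20
    occasion_length: int = 6
    covariate_names: tuple[str, ...] = (
        "large_stem_density", "small_stem_density", "canopy_height_mean",
        "canopy_height_sd", "shannon_h", "trail_width_max", "undergrowth_mean",
    )
    collinear_pair: tuple[str, str] | None = None
    collinear_r: float = 0.8
    species: tuple[SpeciesScenario, ...] = ()
    two_species: TwoSpeciesBlock | None = None
    start_date: datetime = datetime(2013, 1, 15)
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated records."""

    occupancy: dict[str, np.ndarray]
    scenario: SimScenario
    true_phi: float | None = None
    true_delta: float | None = None


# ---------------------------------------------------------------------------
# stations, effort, covariates
# ---------------------------------------------------------------------------

def simulate_stations(scenario: SimScenario, rng: np.random.Generator | None = None,
                      ) -> tuple[list[StationEffort], pd.DataFrame]:
    """Draw operational windows (truncated normal durations) and a station
    covariate table (standard normal, with an optional built-in collinear
    pair to exercise screening)."""
    rng = rng or np.random.default_rng(scenario.seed)
    efforts = []
    for i in range(scenario.n_stations):
        days = scenario.min_days - 1
        while days < scenario.min_days:
            days = int(round(rng.normal(scenario.mean_days, scenario.sd_days)))
        deploy = scenario.start_date + timedelta(days=int(rng.integers(0, 30)))
        retrieve = deploy + timedelta(days=days - 1)
        efforts.append(StationEffort(f"st{i + 1:03d}", deploy, retrieve))

    n = scenario.n_stations
    cov = pd.DataFrame(
        rng.standard_normal((n, len(scenario.covariate_names))),
        columns=list(scenario.covariate_names),
        index=[e.station_id for e in efforts],
    )
    cov.index.name = "station"
    if scenario.collinear_pair is not None:
        a, b = scenario.collinear_pair
        r = scenario.collinear_r
        cov[b] = r * cov[a] + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
    cov["season"] = np.where(rng.random(n) < 0.5, "wet", "dry")
    return efforts, cov


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------

def _linpred(coefs: dict[str, float], covariates: pd.DataFrame,
             stations: list[str]) -> np.ndarray:
    eta = np.full(len(stations), coefs.get("(intercept)", 0.0))
    for name, value in coefs.items():
        if name == "(intercept)":
            continue
        col = covariates.loc[stations, name]
        if col.dtype == object:
            col = (col == sorted(col.unique())[-1]).astype(float)
        eta = eta + value * col.to_numpy(dtype=float)
    return eta


def simulate_activity_times(mixture: ActivityMixture, n: int,
                            rng: np.random.Generator | int) -> np.ndarray:
    """Draw ``n`` circular times (radians) from a von Mises mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    weights = np.array([w for _, _, w in mixture], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    comp = rng.choice(len(mixture), size=n, p=weights)
    out = np.empty(n)
    for j, (mu, kappa, _w) in enumerate(mixture):
        mask = comp == j
        if mask.any():
            out[mask] = rng.vonmises(mu - np.pi, kappa, size=int(mask.sum())) + np.pi
    return np.mod(out, TWO_PI)


def _daily_rate(p_occasion: np.ndarray, occasion_length: int) -> np.ndarray:
    return 1.0 - (1.0 - p_occasion) ** (1.0 / occasion_length)


def _emit_record(rows: list, effort: StationEffort, species: str,
                 day: int, theta: float) -> None:
    hours = theta * 24.0 / TWO_PI
    ts = (effort.deploy + timedelta(days=int(day))
          + timedelta(hours=float(hours)))
    # clamp inside the operational window (minute resolution)
    ts = min(max(ts, effort.deploy), effort.retrieve)
    rows.append({"station": effort.station_id, "species": species,
                 "timestamp": ts.replace(second=0, microsecond=0)})


def simulate_detections(scenario: SimScenario, efforts: list[StationEffort],
                        covariates: pd.DataFrame,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a record table plus ground truth.

    Independent species blocks: latent occupancy from psi(covariates), then
    daily Bernoulli detections at the converted daily rate, each with a
    timestamp drawn from the species' activity mixture. The two-species
    block draws the four-state occupancy jointly and applies conditional
    detection at occasion granularity (one record per detected occasion).
    """
    rng = rng or np.random.default_rng(scenario.seed + 1)
    stations = [e.station_id for e in efforts]
    rows: list[dict] = []
    truth = SimTruth(occupancy={}, scenario=scenario)

    for sp in scenario.species:
        psi = expit(_linpred(sp.psi_coefs, covariates, stations))
        p_occ = expit(_linpred(sp.p_coefs, covariates, stations))
        q = _daily_rate(p_occ, scenario.occasion_length)
        z = rng.random(len(stations)) < psi
        truth.occupancy[sp.name] = z.astype(int)
        for i, eff in enumerate(efforts):
            if not z[i]:
                continue
            mask = eff.day_active_mask()
            hits = np.flatnonzero(rng.random(mask.size) < q[i]) if q[i] > 0 else []
            for day in hits:
                if mask[day]:
                    theta = simulate_activity_times(sp.activity, 1, rng)[0]
                    _emit_record(rows, eff, sp.name, int(day), theta)

    block = scenario.two_species
    if block is not None:
        known = {sp.name for sp in scenario.species}
        for name in (block.species_a, block.species_b):
            if name in known:
                raise ValueError(
                    f"two-species block species {name!r} duplicates an "
                    "independent species block")
        _simulate_two_species(block, scenario, efforts, rng, rows, truth)
        truth.true_phi = block.true_phi
        truth.true_delta = block.true_delta

    records = pd.DataFrame(rows, columns=["station", "species", "timestamp"])
    if not records.empty:
        records = records.sort_values(
            ["station", "species", "timestamp"]).reset_index(drop=True)
    return records, truth


def _simulate_two_species(block: TwoSpeciesBlock, scenario: SimScenario,
                          efforts: list[StationEffort],
                          rng: np.random.Generator, rows: list,
                          truth: SimTruth) -> None:
    length = scenario.occasion_length
    n = len(efforts)
    za = rng.random(n) < block.psiA
    psi_b = np.where(za, block.psiBA, block.psiBa)
    zb = rng.random(n) < psi_b
    truth.occupancy[block.species_a] = za.astype(int)
    truth.occupancy[block.species_b] = zb.astype(int)

    for i, eff in enumerate(efforts):
        mask = eff.day_active_mask()
        n_occ = int(np.ceil(mask.size / length))
        for k in range(n_occ):
            days = np.flatnonzero(mask[k * length : (k + 1) * length])
            if days.size == 0:
                continue
            det_a = False
            if za[i]:
                pa = block.rA if zb[i] else block.pA
                det_a = bool(rng.random() < pa)
            det_b = False
            if zb[i]:
                if za[i]:
                    pb = block.rBA if det_a else block.rBa
                else:
                    pb = block.pB
                det_b = bool(rng.random() < pb)
            if det_a:
                day = k * length + int(rng.choice(days))
                theta = simulate_activity_times(block.activity_a, 1, rng)[0]
                _emit_record(rows, eff, block.species_a, day, theta)
            if det_b:
                day = k * length + int(rng.choice(days))
                theta = simulate_activity_times(block.activity_b, 1, rng)[0]
                _emit_record(rows, eff, block.species_b, day, theta)


# ---------------------------------------------------------------------------
# occasion-level shortcuts (used heavily by tests and calibration runs)
# ---------------------------------------------------------------------------

def simulate_history_matrix(n_sites: int, n_occasions: int, psi, p,
                            rng: np.random.Generator | int) -> np.ndarray:
    """Occupancy detection matrix straight at occasion resolution."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (n_sites,))
    p = np.broadcast_to(np.asarray(p, dtype=float), (n_sites, n_occasions))
    z = rng.random(n_sites) < psi
    return ((rng.random((n_sites, n_occasions)) < p) & z[:, None]).astype(float)


def simulate_two_species_matrices(n_sites: int, n_occasions: int,
                                  block: TwoSpeciesBlock,
                                  rng: np.random.Generator | int,
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Paired detection matrices under the conditional two-species model."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    za = rng.random(n_sites) < block.psiA
    zb = rng.random(n_sites) < np.where(za, block.psiBA, block.psiBa)
    pa = np.where(zb, block.rA, block.pA)
    ya = (rng.random((n_sites, n_occasions)) < pa[:, None]) & za[:, None]
    pb_both = np.where(ya, block.rBA, block.rBa)
    pb = np.where(za[:, None], pb_both, block.pB)
    yb = (rng.random((n_sites, n_occasions)) < pb) & zb[:, None]
    return ya.astype(float), yb.astype(float)


def default_scenario(seed: int = 0) -> SimScenario:
    """A three-species scenario with habitat-driven occupancy, a collinear
    covariate pair, a two-species avoidance block, and contrasting diel
    patterns — enough structure to exercise every pipeline stage."""
    species = (
        SpeciesScenario(
            name="forest_genet",
            psi_coefs={"(intercept)": 0.4, "shannon_h": 0.8},
            p_coefs={"(intercept)": -0.7, "trail_width_max": 0.5},
            activity=NOCTURNAL_BIMODAL,
        ),
        SpeciesScenario(
            name="marsh_mongoose",
            psi_coefs={"(intercept)": 1.5},
            p_coefs={"(intercept)": 0.2},
            activity=DIURNAL,
        ),
    )
    block = TwoSpeciesBlock(
        species_a="golden_cat", species_b="civet",
        psiA=0.55, psiBA=0.25, psiBa=0.7,
        pA=0.3, pB=0.35, rA=0.3, rBA=0.35, rBa=0.35,
    )
    return SimScenario(
        species=species, two_species=block,
        collinear_pair=("large_stem_density", "canopy_height_mean"),
        seed=seed,
    )
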