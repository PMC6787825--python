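from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from camtrapniche.detections import StationEffort


@pytest.fixture
def small_efforts() -> list[StationEffort]:
    """Three stations, 76/30/12 operational days, one with a failure gap."""
    return [
        StationEffort("A", datetime(2013, 2, 1), datetime(2013, 4, 17)),   # 76 days
        StationEffort("B", datetime(2013, 2, 10), datetime(2013, 3, 11)),  # 30 days
        StationEffort(
            "C", datetime(2013, 2, 1), datetime(2013, 2, 12),              # 12 days
            inactive_intervals=((datetime(2013, 2, 4), datetime(2013, 2, 6)),),
        ),
    ]


@pytest.fixture
def small_records() -> pd.DataFrame:
    return pd.DataFrame({
        "station": ["A", "A", "A", "B", "C"],
        "species": ["civet", "civet", "genet", "civet", "genet"],
        "timestamp": pd.to_datetime([
            "2013-02-08T21:00",   # day 7 after deployment of A
            "2013-02-08T23:30",
            "2013-02-02T02:15",
            "2013-02-20T19:45",
            "2013-02-03T01:00",
        ]),
    })


def enumeration_loglik(y: np.ndarray, active: np.ndarray, psi: np.ndarray,
                       p: np.ndarray) -> float:
    """Independent oracle: sum the likelihood over latent states z in {0,1}
    per site, term by term."""
    total = 0.0
    n, k = y.shape
    for i in range(n):
        if not active[i].any():
            continue
        lik = 0.0
        for z in (0, 1):
            term = psi[i] if z == 1 else 1.0 - psi[i]
            for j in range(k):
                if not active[i, j]:
                    continue
                if z == 1:
                    term *= p[i, j] if y[i, j] == 1 else 1.0 - p[i, j]
                elif y[i, j] == 1:
                    term = 0.0
            lik += term
        total += np.log(lik)
    return total


def enumeration_two_species(ya, yb, active, pr) -> float:
    """Oracle: brute-force sum over the four latent (zA, zB) states."""
    total = 0.0
    n, k = ya.shape
    for i in range(n):
        if not active[i].any():
            continue
        lik = 0.0
        for za in (0, 1):
            for zb in (0, 1):
                w = (pr["psiA"] if za else 1 - pr["psiA"])
                if za:
                    w *= pr["psiBA"] if zb else 1 - pr["psiBA"]
                else:
                    w *= pr["psiBa"] if zb else 1 - pr["psiBa"]
                term = w
                for j in range(k):
                    if not active[i, j]:
                        continue
                    da, db = ya[i, j] == 1, yb[i, j] == 1
                    if za and zb:
                        term *= pr["rA"] if da else 1 - pr["rA"]
                        rb = pr["rBA"] if da else pr["rBa"]
                        term *= rb if db else 1 - rb
                    elif za and not zb:
                        term *= pr["pA"] if da else 1 - pr["pA"]
                        if db:
                            term = 0.0
                    elif not za and zb:
                        if da:
                            term = 0.0
                        term *= pr["pB"] if db else 1 - pr["pB"]
                    else:
                        if da or db:
                            term = 0.0
                lik += term
        total += np.log(lik)
    return total
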