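"""Small builders shared across test modules."""

import datetime as dt

import numpy as np

from gwrpm25.data_model import ModelRow

DAY = dt.date(2015, 4, 10)


def rows_from_arrays(X, y, lonlat):
    rows = []
    for i in range(len(y)):
        rows.append(
            ModelRow(
                station_id=f"S{i:03d}",
                lon=float(lonlat[i, 0]),
                lat=float(lonlat[i, 1]),
                day=DAY,
                revised_aod=float(X[i, 1]),
                last_prec=float(X[i, 2]),
                st=float(X[i, 3]),
                ps=float(X[i, 4]),
                ws=float(X[i, 5]),
                rh=50.0,
                pblh=1.0,
                revised_pm25=float(y[i]),
                pm25=float(max(y[i], 0.0)) * 0.5,
            )
        )
    return rows


def synthetic_rows(n, seed, noise=5.0, beta=(30.0, 80.0, -1.5, 0.3, -4e-4, -2.0)):
    """Rows with realistic regressor ranges and a global linear response."""
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [
            np.ones(n),
            rng.uniform(0.2, 1.5, n),
            np.where(rng.random(n) < 0.7, 0.0, rng.exponential(4.0, n)),
            rng.normal(290.0, 8.0, n),
            rng.normal(95000.0, 3000.0, n),
            rng.uniform(0.0, 8.0, n),
        ]
    )
    lonlat = np.column_stack([rng.uniform(100, 104, n), rng.uniform(32, 36, n)])
    y = X @ np.asarray(beta) + rng.normal(0, noise, n)
    return rows_from_arrays(X, y, lonlat)
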