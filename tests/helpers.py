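"""Shared constructors for small in-memory logs used across test modules."""

import numpy as np
import pandas as pd

from sgrt_dynqa import SurfaceLog, TrajectoryLog
from sgrt_dynqa.log_io import SURF_COLUMNS, TRAJ_COLUMNS


def make_traj(n, dt=0.02, mu=None, **overrides):
    cols = {"t": np.arange(n) * dt}
    for c in TRAJ_COLUMNS:
        cols[c] = np.zeros(n)
    cols["mu"] = np.zeros(n) if mu is None else np.asarray(mu, dtype=float)
    cols.update(overrides)
    return TrajectoryLog(sample_interval_s=dt, data=pd.DataFrame(cols))


def make_surf(t, **axes):
    cols = {"t": np.asarray(t, dtype=float)}
    for c in SURF_COLUMNS:
        cols[c] = np.asarray(axes.get(c, np.zeros(len(cols["t"]))), dtype=float)
    return SurfaceLog(data=pd.DataFrame(cols))
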