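"""Harvest index estimation from predicted yield and biomass.

HI is predicted lint yield over the season maximum of the predicted
biomass trajectory (both kg ha⁻¹; biomass predictions in g m⁻² are
converted by the factor 10). Predicted HI is evaluated against measured
HI per season (squared Pearson correlation and RMSE), since the
yield/biomass error structure can differ between seasons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from cottonphys.exceptions import DegenerateInputError
from cottonphys.radiation import G_M2_TO_KG_HA

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HIEstimate:
    plot_id: str
    season: str
    hi_pred: float
    hi_meas: float


def predict_hi(
    yield_pred_kg_ha: float, biomass_pred_series_g_m2: Sequence[float]
) -> float:
    """Predicted HI: yield over 10 × max of the predicted biomass series."""
    if len(biomass_pred_series_g_m2) == 0:
        raise DegenerateInputError("empty predicted-biomass series")
    max_biomass = max(biomass_pred_series_g_m2) * G_M2_TO_KG_HA
    if max_biomass <= 0:
        raise DegenerateInputError("maximum predicted biomass is not positive")
    return yield_pred_kg_ha / max_biomass


def evaluate_hi(
    estimates: Sequence[HIEstimate], group_by: str = "season"
) -> pd.DataFrame:
    """Per-group (and pooled) R² and RMSE of predicted vs measured HI.

    Groups with fewer than 3 estimates are skipped with a log message.
    Returns a frame with columns group, n, r2, rmse; the pooled row has
    group ``"pooled"``.
    """
    df = pd.DataFrame([e.__dict__ for e in estimates])
    if df.empty:
        raise DegenerateInputError("no HI estimates to evaluate")
    rows = []
    groups = [(g, sub) for g, sub in df.groupby(group_by, sort=True)]
    groups.append(("pooled", df))
    for name, sub in groups:
        if len(sub) < 3:
            logger.info("HI group %s has %d (<3) estimates; skipped", name, len(sub))
            continue
        pred = sub["hi_pred"].to_numpy(dtype=float)
        meas = sub["hi_meas"].to_numpy(dtype=float)
        rmse = float(np.sqrt(np.mean((pred - meas) ** 2)))
        if np.all(pred == pred[0]) or np.all(meas == meas[0]):
            r2 = float("nan")
        else:
            r = float(np.corrcoef(pred, meas)[0, 1])
            r2 = r * r
        rows.append({"group": name, "n": len(sub), "r2": r2, "rmse": rmse})
    return pd.DataFrame(rows)
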