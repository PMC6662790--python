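"""QTc phenotype simulation.

Penetrant carriers draw their QTc from the carrier distribution, everyone
else from the non-carrier distribution.  The emitted (QT, RR) pair is
constructed so that Bazett's correction recovers the drawn QTc exactly:
``qt_ms = qtc_ms * sqrt(rr_s)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import ValidationError
from .config import QtcModel

__all__ = ["simulate_qtc"]


def simulate_qtc(
    ids: list[str],
    carrier_flags: np.ndarray,
    model: QtcModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """ECG table with columns id, qt_ms, rr_s, qtc_ms (the drawn truth)."""
    model.validate()
    carrier_flags = np.asarray(carrier_flags, dtype=bool)
    if carrier_flags.shape != (len(ids),):
        raise ValidationError("carrier flags must align with ids")
    n = len(ids)
    penetrant = carrier_flags & (rng.random(n) < model.penetrance)
    means = np.where(penetrant, model.carrier_mean_ms, model.noncarrier_mean_ms)
    qtc = rng.normal(means, model.sd_ms)
    rr = rng.uniform(0.6, 1.2, n)
    qt = qtc * np.sqrt(rr)
    return pd.DataFrame(
        {"id": ids, "qt_ms": qt, "rr_s": rr, "qtc_ms": qtc, "carrier": carrier_flags}
    )
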