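"""Species specialization index (SSI).

A species occupying ``h`` of ``H`` possible classes (habitat or diet) has

    SSI = sqrt(H / h - 1)

which is algebraically identical to the population coefficient of
variation (SD / mean, with divisor ``H``) of the species' binary
presence/absence vector across the ``H`` classes.  SSI is 0 for a complete
generalist (h = H) and maximal, sqrt(H - 1), for a species confined to a
single class.

``H`` is the number of classes in the preference taxonomy (15 habitat,
9 diet classes by default), not the number of classes observed in any
particular census — specialization is a property of the species, measured
independently of local habitat availability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedSpecializationError(ValueError):
    """Raised when a species occupies no class at all (h = 0)."""


@dataclass(frozen=True)
class SSIResult:
    species: str
    domain: str
    h: int
    H: int
    ssi: float


def compute_ssi(h: int, H: int) -> float:
    """Specialization index for a species occupying ``h`` of ``H`` classes.

    Parameters
    ----------
    h : int
        Number of occupied classes, ``1 <= h <= H``.
    H : int
        Number of possible classes.

    Returns
    -------
    float
        ``sqrt(H / h - 1)``.
    """
    h = int(h)
    H = int(H)
    if H < 1:
        raise ValueError(f"H must be a positive integer, got {H}")
    if h == 0:
        raise UndefinedSpecializationError(
            "species occupies no class (h = 0); SSI is undefined"
        )
    if h < 0 or h > H:
        raise ValueError(f"h must satisfy 1 <= h <= H, got h={h}, H={H}")
    return float(np.sqrt(H / h - 1.0))


def ssi_from_vector(presence, species: str = "", domain: str = "") -> SSIResult:
    """SSI from a binary presence/absence vector over all ``H`` classes."""
    vec = np.asarray(presence)
    if vec.ndim != 1:
        raise ValueError("presence vector must be one-dimensional")
    if not np.isin(vec, (0, 1)).all():
        raise ValueError("presence vector entries must be 0 or 1")
    H = vec.size
    h = int(vec.sum())
    if h == 0:
        raise UndefinedSpecializationError(
            f"species {species!r} occupies no class; SSI is undefined"
        )
    return SSIResult(species=species, domain=domain, h=h, H=H, ssi=compute_ssi(h, H))


def ssi_table(prefs: pd.DataFrame, domain: str) -> pd.DataFrame:
    """Per-species SSI from a species x class binary preference table.

    Returns a frame indexed like ``prefs`` with columns ``h_<domain>`` and
    ``ssi_<domain>``.
    """
    results = {
        sp: ssi_from_vector(row.to_numpy(), species=str(sp), domain=domain)
        for sp, row in prefs.iterrows()
    }
    return pd.DataFrame(
        {
            f"h_{domain}": {sp: r.h for sp, r in results.items()},
            f"ssi_{domain}": {sp: r.ssi for sp, r in results.items()},
        }
    ).loc[prefs.index]
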