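"""Trait reduction and predictor preparation.

Morphological traits (body, wing, tail, bill and tarsus length) and
reproductive traits (clutch size, broods per year, egg mass, life span)
are each collapsed to their first principal component: a structural-size
axis (ssPC) and a slow-fast life-history axis (sfPC).  PCA is run on the
correlation matrix (traits are z-standardized first) because the blocks
mix millimetres, grams and years; a covariance-matrix PCA would be
dominated by whichever trait has the largest unit variance.

Body mass enters the models separately (log scale) because it correlates
with both PC axes; ssPC and sfPC are never used in the same model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .habitats import NEST_TYPES

logger = logging.getLogger(__name__)

MORPHOLOGY_TRAITS = [
    "body_length",
    "wing_length",
    "tail_length",
    "bill_length",
    "tarsus_length",
]
REPRODUCTIVE_TRAITS = ["clutch_size", "broods_per_year", "egg_mass", "life_span"]


@dataclass
class PCResult:
    """First-principal-component summary of a trait block."""

    scores: pd.Series
    loadings: pd.Series
    variance_explained_pc1: float
    eigenvalues: np.ndarray = field(repr=False, default=None)


def sex_average(traits: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Average ``<trait>_f`` / ``<trait>_m`` column pairs into ``<trait>``.

    Columns already present un-suffixed are passed through.  Averaging
    happens on the raw scale, before any transform.
    """
    out = traits.copy()
    for col in columns:
        if col in out.columns:
            continue
        f, m = f"{col}_f", f"{col}_m"
        if f in out.columns and m in out.columns:
            out[col] = (out[f] + out[m]) / 2.0
        else:
            raise ValueError(f"trait {col!r} not found (nor {f}/{m})")
    return out


def pca_reduce(block: pd.DataFrame, standardize: bool = True) -> PCResult:
    """First principal component of a species x trait block.

    Traits are z-standardized by default (correlation-matrix PCA).  The
    PC1 sign is oriented so its loading on the first column is positive.
    Rows with missing values are dropped with a warning (their scores are
    NaN in the output).
    """
    if block.shape[1] < 2:
        raise ValueError("PCA needs at least two traits")
    complete = block.dropna()
    if complete.shape[0] < block.shape[0]:
        logger.warning(
            "PCA: dropped %d species with missing trait values",
            block.shape[0] - complete.shape[0],
        )
    if complete.shape[0] < 2:
        raise ValueError("PCA needs at least two complete species rows")
    X = complete.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            dead = [c for c, s in zip(complete.columns, sd) if s == 0]
            raise ValueError(f"constant trait column(s): {dead}")
        X = X / sd
    # SVD of the centred (scaled) matrix: right singular vectors are the
    # eigenvectors of the correlation/covariance matrix.
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    pc1 = Vt[0]
    if pc1[0] < 0:
        pc1 = -pc1
    scores = pd.Series(X @ pc1, index=complete.index, name="pc1").reindex(block.index)
    return PCResult(
        scores=scores,
        loadings=pd.Series(pc1, index=block.columns, name="pc1_loading"),
        variance_explained_pc1=float(100.0 * eigvals[0] / eigvals.sum()),
        eigenvalues=eigvals,
    )


def nest_dummies(nest_type: pd.Series) -> pd.DataFrame:
    """Treatment-coded nest-type dummies with ground (G) as reference."""
    bad = set(nest_type.unique()) - set(NEST_TYPES)
    if bad:
        raise ValueError(f"unknown nest type(s): {sorted(bad)}")
    dummies = pd.DataFrame(
        {f"nest_{lvl}": (nest_type == lvl).astype(float) for lvl in NEST_TYPES[1:]}
    )
    return dummies


def prepare_predictors(
    traits: pd.DataFrame,
    ssi: pd.DataFrame,
    ss_pc: PCResult,
    sf_pc: PCResult,
    log_base: str = "natural",
    include_forest_dependency: bool = False,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assemble the per-species predictor table for the regressions.

    Returns the predictor frame and the pairwise correlations (body mass
    vs each PC, and between the PCs) that motivate keeping body mass out
    of the multi-predictor models.
    """
    unmatched = sorted(set(traits.index) ^ set(ssi.index))
    if unmatched:
        raise ValueError(f"species keys do not align across tables: {unmatched}")
    log = np.log if log_base == "natural" else np.log10
    pred = pd.DataFrame(index=traits.index)
    pred["log_body_mass"] = log(traits["body_mass"].astype(float))
    pred["ssPC"] = ss_pc.scores.reindex(traits.index)
    pred["sfPC"] = sf_pc.scores.reindex(traits.index)
    pred["ssi_habitat"] = ssi["ssi_habitat"].reindex(traits.index)
    pred["ssi_diet"] = ssi["ssi_diet"].reindex(traits.index)
    pred["breeding_range"] = traits["breeding_range"].astype(float)
    pred = pred.join(nest_dummies(traits["nest_type"]).set_axis(traits.index))
    if include_forest_dependency and "forest_dependency" in traits.columns:
        pred["forest_dependency"] = traits["forest_dependency"].astype(float)

    corrs = {
        "log_body_mass_vs_ssPC": float(pred["log_body_mass"].corr(pred["ssPC"])),
        "log_body_mass_vs_sfPC": float(pred["log_body_mass"].corr(pred["sfPC"])),
        "ssPC_vs_sfPC": float(pred["ssPC"].corr(pred["sfPC"])),
    }
    logger.info("predictor correlations: %s", corrs)
    return pred, corrs
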