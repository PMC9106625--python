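"""Retention-time modelling for homologous phospholipid series.

On a reversed-phase gradient, phosphatidylcholines (PC), lysoPCs and PC
plasmalogens of one class form homologous series: each added acyl carbon
lowers polarity and raises retention time stepwise, while each added double
bond lowers it.  A per-class ordinary least squares fit of retention time on
(total acyl carbons, double bonds) therefore supports annotation: a
candidate identity is *consistent* when its observed retention time falls
inside the model's prediction interval.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CalibrationError, SchemaError

log = logging.getLogger(__name__)

SPECIES_COLUMNS = ["lipid_class", "carbons", "double_bonds", "rt", "mz"]


def load_reference_lipids() -> pd.DataFrame:
    """Packaged table of identified serum phospholipids and related
    metabolites with observed retention times and masses, used as the
    default calibration/demo species set."""
    ref = importlib.resources.files("metabodcv.data") / "reference_lipids.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_species_table(str(path))


def read_species_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"species table lacks columns {missing}")
    if (df["carbons"] <= 0).any() or (df["double_bonds"] < 0).any():
        raise SchemaError("carbons must be > 0 and double_bonds >= 0")
    return df


@dataclass
class RTModel:
    """OLS calibration of retention time on carbons and double bonds."""

    lipid_class: str
    intercept: float
    beta_carbons: float
    beta_double_bonds: float
    se: np.ndarray  # standard errors (intercept, carbons, double bonds)
    r_squared: float
    resid_df: int
    slopes_plausible: bool  # beta_carbons > 0 and beta_double_bonds < 0
    carbon_range: tuple[float, float]
    db_range: tuple[float, float]
    _fit: object = None


def fit_rt_model(species: pd.DataFrame, lipid_class: str | None = None) -> RTModel:
    """Fit rt ~ carbons + double_bonds by OLS for one lipid class.

    Requires >= 3 species spanning >= 2 distinct carbon counts.  Fitted
    slopes with unexpected signs (non-positive carbon slope or non-negative
    double-bond slope) are flagged, not rejected: the calibration may simply
    be too narrow.
    """
    df = species if lipid_class is None else species[species["lipid_class"] == lipid_class]
    if lipid_class is None:
        classes = df["lipid_class"].unique()
        if len(classes) != 1:
            raise CalibrationError(f"species table mixes classes {list(classes)}")
        lipid_class = classes[0]
    if len(df) < 3:
        raise CalibrationError(f"{lipid_class}: need >= 3 species, got {len(df)}")
    if df["carbons"].nunique() < 2:
        raise CalibrationError(f"{lipid_class}: need >= 2 distinct carbon counts")
    X = sm.add_constant(df[["carbons", "double_bonds"]].to_numpy(float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CalibrationError(f"{lipid_class}: rank-deficient calibration design")
    fit = sm.OLS(df["rt"].to_numpy(float), X).fit()
    b0, bc, bd = fit.params
    plausible = bc > 0 and bd < 0
    if not plausible:
        log.warning(
            "%s: fitted slopes have unexpected signs (carbons %.4f, double bonds %.4f)",
            lipid_class, bc, bd,
        )
    return RTModel(
        lipid_class=lipid_class,
        intercept=float(b0),
        beta_carbons=float(bc),
        beta_double_bonds=float(bd),
        se=np.asarray(fit.bse),
        r_squared=float(fit.rsquared),
        resid_df=int(fit.df_resid),
        slopes_plausible=plausible,
        carbon_range=(float(df["carbons"].min()), float(df["carbons"].max())),
        db_range=(float(df["double_bonds"].min()), float(df["double_bonds"].max())),
        _fit=fit,
    )


@dataclass
class RTPrediction:
    rt: float
    interval: tuple[float, float]
    extrapolated: bool


def predict_rt(
    model: RTModel, carbons: float, double_bonds: float, level: float = 0.95
) -> RTPrediction:
    """Point prediction and prediction interval for one species.

    Predictions outside the calibrated carbon/double-bond range are flagged
    as extrapolated.
    """
    x = np.array([[1.0, carbons, double_bonds]])
    pred = model._fit.get_prediction(x)
    frame = pred.summary_frame(alpha=1 - level)
    extrap = not (
        model.carbon_range[0] <= carbons <= model.carbon_range[1]
        and model.db_range[0] <= double_bonds <= model.db_range[1]
    )
    if extrap:
        log.warning(
            "%s prediction at (C=%s, DB=%s) extrapolates beyond calibration",
            model.lipid_class, carbons, double_bonds,
        )
    return RTPrediction(
        rt=float(frame["mean"].iloc[0]),
        interval=(float(frame["obs_ci_lower"].iloc[0]), float(frame["obs_ci_upper"].iloc[0])),
        extrapolated=extrap,
    )


def annotation_eligible(signal_area, min_area: float = 100.0):
    """MS/MS identification eligibility: fragmentation spectra are not
    informative below ~100 counts of signal area, so such features are
    flagged ineligible (they stay in the data set; this gates identification
    only)."""
    return np.asarray(signal_area, float) >= min_area


def consistency_report(
    model: RTModel, candidates: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Check candidate annotations against the calibration.

    Each row of ``candidates`` (same columns as a species table) gets a
    predicted retention time, prediction interval, and a ``consistent`` flag
    (observed rt inside the interval).
    """
    rows = []
    for _, row in candidates.iterrows():
        pred = predict_rt(model, row["carbons"], row["double_bonds"], level)
        rows.append(
            {
                "lipid_class": row["lipid_class"],
                "carbons": row["carbons"],
                "double_bonds": row["double_bonds"],
                "rt_observed": row["rt"],
                "rt_predicted": pred.rt,
                "interval_low": pred.interval[0],
                "interval_high": pred.interval[1],
                "extrapolated": pred.extrapolated,
                "consistent": bool(pred.interval[0] <= row["rt"] <= pred.interval[1]),
            }
        )
    return pd.DataFrame(rows)
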