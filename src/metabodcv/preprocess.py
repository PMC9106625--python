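"""Feature-table cleanup and correction for untargeted LC-MS data.

Implements the standard post-peak-picking stages for a serum metabolomics
study: removal of blank-borne features, chromatographic retention-time
windowing, an early-eluting mass-defect plausibility filter, isotope and
duplicate removal, ratio-based inter-batch correction, QC-pool LOWESS
intra-batch drift correction, correlation-based feature grouping,
ionization-mode concatenation, and per-subject baseline subtraction.

The filters are applied in the order blank -> RT window -> mass defect ->
isotopes/duplicates; each is idempotent.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigurationError, PairingError, PreconditionError
from .synthetic import ISOTOPE_SPACING
from .tables import BLANK, QC_POOL, SAMPLE, FeatureTable, FilterReport, align_samples

log = logging.getLogger(__name__)


def _report(stage, before_ids, after_ids, detail=None):
    removed = [i for i in before_ids if i not in set(after_ids)]
    return FilterReport(
        stage=stage,
        removed_ids=removed,
        n_before=len(before_ids),
        n_after=len(after_ids),
        detail=detail or {},
    )


def filter_blank_features(
    table: FeatureTable, ratio_threshold: float = 0.5
) -> tuple[FeatureTable, FilterReport]:
    """Remove features present in procedural blanks.

    "Present in blanks" is operationalized as mean blank intensity strictly
    greater than ``ratio_threshold`` times the mean study-sample intensity
    (absolute presence is meaningless above a noise floor).
    """
    blank_cols = table.sample_ids_of_type(BLANK)
    if not blank_cols:
        raise PreconditionError("filter_blank_features requires at least one blank sample")
    study_cols = table.study_sample_ids
    blank_mean = table.intensities[blank_cols].mean(axis=1)
    study_mean = table.intensities[study_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = blank_mean / study_mean
    ratio = ratio.where(study_mean > 0, np.where(blank_mean > 0, np.inf, 0.0))
    keep = table.feature_ids[~(ratio > ratio_threshold)]
    out = table.subset_features(keep)
    return out, _report("blank", table.feature_ids, keep)


def filter_rt_window(
    table: FeatureTable, rt_min: float = 0.3, rt_max: float = 9.42
) -> tuple[FeatureTable, FilterReport]:
    """Retain features eluting inside the closed window [rt_min, rt_max] min."""
    if rt_min > rt_max:
        raise ConfigurationError("rt_min must not exceed rt_max")
    keep = table.feature_ids[(table.features["rt"] >= rt_min) & (table.features["rt"] <= rt_max)]
    return table.subset_features(keep), _report("rt_window", table.feature_ids, keep)


def filter_early_mass_defect(table: FeatureTable) -> tuple[FeatureTable, FilterReport]:
    """Remove implausible early-eluting features.

    In the 0.3-0.8 min dead-volume region, genuine small polar metabolites
    have small mass defects; features whose m/z first decimal digit is 4-9
    (fractional part in [0.4, 1.0)) are removed.
    """
    rt = table.features["rt"]
    frac = table.features["mz"] % 1.0
    bad = (rt >= 0.3) & (rt <= 0.8) & (frac >= 0.4)
    keep = table.feature_ids[~bad]
    return table.subset_features(keep), _report("mass_defect", table.feature_ids, keep)


def remove_isotopes_duplicates(
    table: FeatureTable,
    mz_tol: float = 0.01,
    rt_tol: float = 0.01,
    corr_min: float = 0.7,
) -> tuple[FeatureTable, FilterReport]:
    """Remove isotope satellites and duplicate features.

    Within ``rt_tol`` of a more intense feature, a feature is an isotope if
    its m/z sits ``k * 1.00336`` Da higher (k = 1, 2; within ``mz_tol``) and
    its study-sample intensity correlates at >= ``corr_min``; features that
    agree in both m/z (<= ``mz_tol``) and RT are duplicates, keeping the most
    intense.  The report's ``detail`` labels each removal.
    """
    if len(table.features) < 2:
        raise PreconditionError("need at least 2 features")
    study_cols = table.study_sample_ids
    inten = table.intensities[study_cols]
    mean_int = inten.mean(axis=1)
    order = mean_int.sort_values(ascending=False).index  # most intense first
    mzs = table.features["mz"]
    rts = table.features["rt"]
    X = inten.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    row_of = {fid: i for i, fid in enumerate(table.feature_ids)}

    removed = {}
    kept = []
    for fid in order:
        if fid in removed:
            continue
        for other in kept:
            if abs(rts[fid] - rts[other]) > rt_tol:
                continue
            dmz = mzs[fid] - mzs[other]
            if abs(dmz) <= mz_tol:
                removed[fid] = "duplicate"  # `other` is at least as intense
                break
            is_iso_spacing = any(
                abs(dmz - k * ISOTOPE_SPACING) <= mz_tol for k in (1, 2)
            )
            if is_iso_spacing:
                i, j = row_of[fid], row_of[other]
                denom = norms[i] * norms[j]
                r = float(Xc[i] @ Xc[j] / denom) if denom > 0 else 0.0
                if r >= corr_min:
                    removed[fid] = "isotope"
                    break
        else:
            kept.append(fid)
    keep = [f for f in table.feature_ids if f not in removed]
    out = table.subset_features(keep)
    return out, _report("isotopes_duplicates", table.feature_ids, keep, detail=removed)


def batch_correct(table: FeatureTable, mode: str = "default") -> FeatureTable:
    """Ratio-based inter-batch correction, per feature.

    ``default`` equalizes per-feature batch means:
    ``corrected = intensity * overall_average / batch_average``.  ``verbatim``
    applies the inverse ratio (* batch / overall), preserved for audits of
    the as-printed formula, which amplifies rather than removes batch
    differences.  Averages are computed over study samples; the factor is
    applied to every injection of the batch (QC pools and blanks included).
    A zero batch average leaves that batch's values untouched with a warning.
    """
    if mode not in ("default", "verbatim"):
        raise ConfigurationError("batch_correct mode must be 'default' or 'verbatim'")
    meta = table.samples.loc[list(table.intensities.columns)]
    study = meta.index[meta["sample_type"] == SAMPLE]
    if len(study) == 0:
        raise PreconditionError("batch_correct requires study samples")
    out = table.copy()
    overall = table.intensities[study].mean(axis=1).to_numpy()
    for b in sorted(meta["batch"].unique()):
        cols = meta.index[meta["batch"] == b]
        study_b = [c for c in cols if c in set(study)]
        if not study_b:
            raise PreconditionError(f"batch {b} has no study samples")
        bmean = table.intensities[study_b].mean(axis=1).to_numpy()
        zero = bmean == 0
        if zero.any():
            log.warning("batch %s: %d features with zero batch average left as-is", b, zero.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = overall / bmean if mode == "default" else bmean / np.where(overall == 0, 1, overall)
        factor = np.where(zero, 1.0, factor)
        out.intensities.loc[:, cols] = out.intensities.loc[:, cols].to_numpy() * factor[:, None]
    return out


def drift_correct(table: FeatureTable, span: float = 0.75) -> FeatureTable:
    """Intra-batch signal-drift correction from repeated QC-pool injections.

    Per feature and batch, a LOWESS curve of QC-pool intensity versus
    injection order (fraction ``span``) is interpolated to every injection
    and normalized to its mean over the batch; all intensities are divided by
    this normalized trend.  Features whose fitted trend is non-positive
    anywhere are left uncorrected with a warning; a batch with fewer than 3
    QC pools is left uncorrected (logged).
    """
    meta = table.samples.loc[list(table.intensities.columns)]
    out = table.copy()
    n_skipped = 0
    for b in sorted(meta["batch"].unique()):
        cols = list(meta.index[meta["batch"] == b])
        qc_cols = [c for c in cols if meta.loc[c, "sample_type"] == QC_POOL]
        if len(qc_cols) < 3:
            log.warning("batch %s: only %d QC pools; drift left uncorrected", b, len(qc_cols))
            continue
        qc_order = meta.loc[qc_cols, "injection_order"].to_numpy(float)
        all_order = meta.loc[cols, "injection_order"].to_numpy(float)
        qc_int = table.intensities[qc_cols].to_numpy()
        block = out.intensities.loc[:, cols].to_numpy()
        for i in range(block.shape[0]):
            fitted = lowess(qc_int[i], qc_order, frac=span, return_sorted=True)
            trend = np.interp(all_order, fitted[:, 0], fitted[:, 1])
            if (trend <= 0).any():
                n_skipped += 1
                continue
            block[i] = block[i] / (trend / trend.mean())
        out.intensities.loc[:, cols] = block
    if n_skipped:
        log.warning("drift_correct: %d feature/batch trends non-positive, left uncorrected", n_skipped)
    return out


def group_features(
    table: FeatureTable, rt_window: float = 0.01, corr_min: float = 0.7
) -> tuple[FeatureTable, FilterReport]:
    """Collapse co-eluting, correlated features (adducts/fragments of one
    compound) by single linkage: features within ``rt_window`` minutes whose
    Pearson correlation over study samples exceeds ``corr_min`` form a group,
    represented by its most intense member."""
    study_cols = table.study_sample_ids
    if len(study_cols) < 3:
        raise PreconditionError("group_features needs >= 3 study samples")
    ids = list(table.feature_ids)
    rts = table.features["rt"].to_numpy()
    X = table.intensities[study_cols].to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)

    parent = list(range(len(ids)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = np.argsort(rts)
    srt = rts[order]
    for a in range(len(order)):
        b = a + 1
        while b < len(order) and srt[b] - srt[a] <= rt_window:
            i, j = order[a], order[b]
            denom = norms[i] * norms[j]
            r = (Xc[i] @ Xc[j] / denom) if denom > 0 else 0.0
            if r > corr_min:
                parent[find(i)] = find(j)
            b += 1

    mean_int = X.mean(axis=1)
    groups = {}
    for i in range(len(ids)):
        groups.setdefault(find(i), []).append(i)
    keep, membership = [], {}
    for members in groups.values():
        rep = max(members, key=lambda i: mean_int[i])
        keep.append(ids[rep])
        if len(members) > 1:
            membership[ids[rep]] = [ids[i] for i in members]
    keep_set = set(keep)
    keep_ordered = [f for f in ids if f in keep_set]
    out = table.subset_features(keep_ordered)
    return out, _report("grouping", ids, keep_ordered, detail={"groups": membership})


def concatenate_modes(pos: FeatureTable, neg: FeatureTable) -> FeatureTable:
    """Row-wise union of the positive- and negative-mode tables, sample
    columns aligned by id (not position)."""
    if len(neg.features) == 0:
        return pos.copy()
    if len(pos.features) == 0:
        return neg.copy()
    align_samples(pos, neg)
    cols = list(pos.intensities.columns)
    neg_int = neg.intensities[[c for c in cols if c in neg.intensities.columns]]
    missing = [c for c in cols if c not in neg.intensities.columns]
    if missing:
        raise PreconditionError(f"negative table lacks non-study columns {missing}")
    feats = pd.concat([pos.features, neg.features])
    if not feats.index.is_unique:
        raise PreconditionError("feature ids clash between modes; make them unique first")
    inten = pd.concat([pos.intensities, neg_int[cols]])
    return FeatureTable(feats, inten, pos.samples.copy(), pos.is_change)


def baseline_subtract(table: FeatureTable) -> FeatureTable:
    """Per-subject baseline correction: one signed column per subject equal
    to week-8 minus baseline intensity, removing stable inter-individual
    differences.  Blanks and QC pools are dropped."""
    meta = table.samples.loc[list(table.intensities.columns)]
    study = meta[meta["sample_type"] == SAMPLE]
    cols = {}
    sample_rows = []
    for subject, grp in study.groupby("subject", sort=True):
        visits = grp["visit"].tolist()
        if sorted(visits) != ["baseline", "week8"]:
            raise PairingError(
                f"subject {subject} lacks a baseline/week8 pair (has {visits})"
            )
        base_col = grp.index[grp["visit"] == "baseline"][0]
        wk_col = grp.index[grp["visit"] == "week8"][0]
        cols[subject] = table.intensities[wk_col] - table.intensities[base_col]
        sample_rows.append(
            (subject, subject, grp["arm"].iloc[0], "week8-baseline", SAMPLE, np.nan, np.nan)
        )
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "subject", "arm", "visit", "sample_type", "batch", "injection_order"],
    ).set_index("sample_id")
    inten = pd.DataFrame(cols, index=table.feature_ids)
    return FeatureTable(table.features.copy(), inten, samples, is_change=True)
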