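"""Synthetic two-arm dietary-intervention metabolomics study generator.

Emulates the data structure of an 8-week parallel-arm trial profiled by
untargeted LC-MS: serum samples at baseline and week 8 for two diet arms
("C" control, "Ex" experimental), blank and pooled-QC injections interleaved
per analytical batch, a planted set of diet-discriminating features, blank-
borne contaminant features, isotope satellite features, and clinical
outcomes whose week-8 change is driven by a latent per-subject diet-response
signal.  A :class:`GroundTruth` record makes every planted structure
recoverable for testing.

Intensities are generated on the log scale (LC-MS intensities are positive
and roughly log-normal) and exponentiated on output.  The per-feature model
for a study sample of subject *s* at visit *v* is::

    log I = mu_f + u_{f,s} + delta_{f,s,v} + eps

with ``mu_f`` the feature's base level, ``u_{f,s}`` a persistent subject
deviation (cancelled by per-subject baseline subtraction), ``eps`` i.i.d.
noise of SD ``noise_sd``, and ``delta`` the planted diet effect: for
discriminating features at week 8 in the Ex arm only,
``delta = sign_f * effect_size * sqrt(2) * noise_sd * c_s`` where ``c_s`` is
the subject's latent compliance (mean 1).  The sqrt(2) factor makes
``effect_size`` the standardized mean difference of the *baseline-corrected*
log intensity between arms, whose noise SD is sqrt(2)*noise_sd.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MetadataError
from .tables import BLANK, QC_POOL, SAMPLE, FeatureTable

#: 13C-12C mass difference (Da) used for isotope satellite features
ISOTOPE_SPACING = 1.00336

#: baseline mean, baseline SD, change residual SD per clinical outcome
#: (mmol/L except insulin in pmol/L); values typical of a moderately
#: hypercholesterolemic adult cohort
OUTCOME_PARAMS = {
    "ldl_c": (4.15, 0.60, 0.30),
    "hdl_c": (1.70, 0.45, 0.20),
    "total_c": (6.60, 0.80, 0.40),
    "tg": (1.25, 0.40, 0.25),
    "glucose": (5.25, 0.40, 0.20),
    "insulin": (50.0, 20.0, 10.0),
}

#: default per-outcome effect of the latent diet signal on the week-8 change
#: (units of the outcome per unit latent signal); the experimental diet
#: lowers LDL, total cholesterol and (slightly) HDL and TG, and leaves
#: glycaemia unchanged
DEFAULT_OUTCOME_BETAS = {
    "ldl_c": -0.40,
    "hdl_c": -0.10,
    "total_c": -0.60,
    "tg": -0.10,
    "glucose": 0.0,
    "insulin": 0.0,
}


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    The defaults define the reference study conditions: 50 subjects per arm,
    500 features split over both ionization modes, 20 discriminating
    features at a standardized baseline-corrected effect of 1.5, three
    analytical batches with multiplicative batch effects and a linear 20%
    intra-batch drift.
    """

    n_subjects_per_arm: int = 50
    n_features_per_mode: tuple[int, int] = (250, 250)  # (positive, negative)
    n_discriminating: int = 20
    effect_size: float = 1.5
    n_blank_features: int = 10
    n_isotope_pairs: int = 10
    n_batches: int = 3
    batch_sd: float = 0.3
    drift_amplitude: float = 0.2
    drift_shape: str = "linear"  # or "quadratic"
    noise_sd: float = 0.25
    subject_sd: float = 0.5
    isotope_fraction: float = 0.3
    compliance_sd: float = 0.25
    outcome_betas: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_BETAS))
    rng_seed: int = 0

    def validate(self) -> None:
        for f in (
            "n_subjects_per_arm",
            "n_discriminating",
            "n_blank_features",
            "n_isotope_pairs",
        ):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")
        if len(self.n_features_per_mode) != 2 or any(
            n < 0 for n in self.n_features_per_mode
        ):
            raise ConfigurationError("n_features_per_mode must be two non-negative counts")
        n_total = sum(self.n_features_per_mode)
        if self.n_discriminating + self.n_blank_features + self.n_isotope_pairs > n_total:
            raise ConfigurationError(
                "n_discriminating + n_blank_features + n_isotope_pairs exceeds "
                "n_features_per_mode total"
            )
        if not np.isfinite(self.effect_size):
            raise ConfigurationError("effect_size must be finite")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")
        if self.drift_shape not in ("linear", "quadratic"):
            raise ConfigurationError("drift_shape must be 'linear' or 'quadratic'")
        for f in ("batch_sd", "drift_amplitude", "noise_sd", "subject_sd"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")


@dataclass
class GroundTruth:
    """Record of every planted structure, for recovery tests."""

    discriminating_ids: list
    blank_ids: list
    isotope_ids: list  # the redundant (satellite) member of each pair
    true_outcome_effects: dict
    effect_signs: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _inject_layout(study_ids, n_batches, rng):
    """Assign study samples to batches in a randomized injection sequence and
    interleave 2 opening blanks plus a QC pool every 10 injections and at the
    batch end (mirroring pooled-sample QC schedules of LC-MS batches)."""
    order = rng.permutation(len(study_ids))
    chunks = np.array_split(order, n_batches)
    rows = []  # (sample_id, sample_type, batch, injection_order)
    for b, chunk in enumerate(chunks, start=1):
        inj = 0
        for r in range(2):
            rows.append((f"BLK_b{b}_{r}", BLANK, b, inj))
            inj += 1
        qc_i = 0
        for k, idx in enumerate(chunk):
            if k % 10 == 0:
                rows.append((f"QC_b{b}_{qc_i}", QC_POOL, b, inj))
                qc_i += 1
                inj += 1
            rows.append((study_ids[idx], SAMPLE, b, inj))
            inj += 1
        rows.append((f"QC_b{b}_{qc_i}", QC_POOL, b, inj))
    return rows


def generate_study(config: SimConfig):
    """Generate one synthetic study.

    Returns ``(table, clinical, truth)``: the feature table (no batch/drift
    distortions applied; use :func:`inject_batch_and_drift` for those — the
    batch and injection-order metadata are already assigned), the wide
    clinical table, and the ground-truth record.  Fully reproducible from
    ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    n_pos, n_neg = config.n_features_per_mode
    n_reg = n_pos + n_neg
    ids = [f"F{i:05d}" for i in range(n_reg)]
    mz = rng.uniform(100.0, 1000.0, n_reg)
    rt = rng.uniform(0.85, 9.30, n_reg)
    mode = np.array(["positive"] * n_pos + ["negative"] * n_neg)

    perm = rng.permutation(n_reg)
    nb, nd, ni = config.n_blank_features, config.n_discriminating, config.n_isotope_pairs
    blank_idx = perm[:nb]
    disc_idx = perm[nb : nb + nd]
    parent_idx = perm[nb + nd : nb + nd + ni]
    signs = rng.choice([-1.0, 1.0], nd)

    # subjects: 1:1 parallel arms
    n_arm = config.n_subjects_per_arm
    subjects = [f"S{i:03d}" for i in range(2 * n_arm)]
    arms = {s: ("C" if i < n_arm else "Ex") for i, s in enumerate(subjects)}
    compliance = {}
    for s in subjects:
        compliance[s] = rng.normal(1.0, config.compliance_sd) if arms[s] == "Ex" else 0.0

    study_ids = [f"{s}_{v}" for s in subjects for v in ("baseline", "week8")]
    layout = _inject_layout(study_ids, config.n_batches, rng)

    sample_meta = pd.DataFrame(
        layout, columns=["sample_id", "sample_type", "batch", "injection_order"]
    ).set_index("sample_id")
    sample_meta["subject"] = [
        i.rsplit("_", 1)[0] if t == SAMPLE else ""
        for i, t in zip(sample_meta.index, sample_meta["sample_type"])
    ]
    sample_meta["visit"] = [
        i.rsplit("_", 1)[1] if t == SAMPLE else ""
        for i, t in zip(sample_meta.index, sample_meta["sample_type"])
    ]
    sample_meta["arm"] = [arms.get(s, "") for s in sample_meta["subject"]]
    sample_meta = sample_meta[
        ["subject", "arm", "visit", "sample_type", "batch", "injection_order"]
    ]

    # log-scale intensity model
    mu = rng.normal(10.0, 1.0, n_reg)
    subj_eff = rng.normal(0.0, config.subject_sd, (n_reg, len(subjects)))
    subj_col = {s: j for j, s in enumerate(subjects)}
    blank_mask = np.zeros(n_reg, dtype=bool)
    blank_mask[blank_idx] = True
    shift_scale = config.effect_size * np.sqrt(2.0) * config.noise_sd

    cols = {}
    for sid, row in sample_meta.iterrows():
        eps = rng.normal(0.0, config.noise_sd, n_reg)
        stype = row["sample_type"]
        if stype == SAMPLE:
            s = row["subject"]
            log_i = mu + subj_eff[:, subj_col[s]] + eps
            if row["visit"] == "week8" and arms[s] == "Ex":
                log_i[disc_idx] += signs * shift_scale * compliance[s]
        elif stype == QC_POOL:
            log_i = mu + eps
        else:  # blank: contaminant features at sample level, rest near noise floor
            log_i = np.where(blank_mask, mu, mu - 5.0) + eps
        cols[sid] = np.exp(log_i)

    features = pd.DataFrame({"mz": mz, "rt": rt, "mode": mode}, index=pd.Index(ids, name="feature_id"))
    intensities = pd.DataFrame(cols, index=features.index)[list(sample_meta.index)]

    # isotope satellite features: +1.00336 Da, same RT, fixed intensity
    # fraction of the parent, near-perfect correlation
    iso_ids = []
    if ni:
        iso_rows, iso_feats = [], []
        for k, pidx in enumerate(parent_idx):
            cid = f"F{n_reg + k:05d}"
            iso_ids.append(cid)
            eps = rng.normal(0.0, 0.01, intensities.shape[1])
            iso_rows.append(
                config.isotope_fraction * intensities.iloc[pidx].to_numpy() * np.exp(eps)
            )
            iso_feats.append((cid, mz[pidx] + ISOTOPE_SPACING, rt[pidx], mode[pidx]))
        iso_feat_df = pd.DataFrame(
            iso_feats, columns=["feature_id", "mz", "rt", "mode"]
        ).set_index("feature_id")
        iso_int_df = pd.DataFrame(
            np.asarray(iso_rows), index=iso_feat_df.index, columns=intensities.columns
        )
        features = pd.concat([features, iso_feat_df])
        intensities = pd.concat([intensities, iso_int_df])

    table = FeatureTable(features, intensities, sample_meta)
    table.validate()

    # clinical outcomes: change = beta * latent signal + noise
    clin = pd.DataFrame(index=pd.Index(subjects, name="subject"))
    clin["arm"] = [arms[s] for s in subjects]
    latent = np.array([compliance[s] for s in subjects])
    for o, (mean, sd, change_sd) in OUTCOME_PARAMS.items():
        base = rng.normal(mean, sd, len(subjects))
        beta = config.outcome_betas.get(o, 0.0)
        change = beta * latent + rng.normal(0.0, change_sd, len(subjects))
        clin[f"{o}_baseline"] = base
        clin[f"{o}_week8"] = base + change

    truth = GroundTruth(
        discriminating_ids=[ids[i] for i in disc_idx],
        blank_ids=[ids[i] for i in blank_idx],
        isotope_ids=iso_ids,
        true_outcome_effects={o: config.outcome_betas.get(o, 0.0) for o in OUTCOME_PARAMS},
        effect_signs={ids[i]: float(s) for i, s in zip(disc_idx, signs)},
    )
    return table, clin, truth


def drift_multiplier(rank: np.ndarray, amplitude: float, shape: str) -> np.ndarray:
    """Smooth monotone drift over normalized injection rank in [0, 1]:
    1 at the first injection, 1 + amplitude at the last."""
    if shape == "quadratic":
        return 1.0 + amplitude * rank**2
    return 1.0 + amplitude * rank


def inject_batch_and_drift(table: FeatureTable, config: SimConfig) -> FeatureTable:
    """Apply multiplicative batch effects and smooth intra-batch drift.

    Each intensity is multiplied by ``exp(g_{f,b})`` with per-(feature, batch)
    factors ``g ~ N(0, batch_sd)``, and by a monotone drift function of the
    within-batch injection rank scaled by ``drift_amplitude``.  QC pools and
    blanks receive the same distortions as study samples.
    """
    config.validate()
    meta = table.samples.loc[list(table.intensities.columns)]
    if meta["batch"].isna().any() or meta["injection_order"].isna().any():
        raise MetadataError("every sample needs batch and injection_order metadata")

    out = table.copy()
    rng = np.random.default_rng([config.rng_seed, 104729])  # independent artifact stream
    batches = sorted(meta["batch"].unique())
    n_feat = len(table.features)
    for b in batches:
        cols = meta.index[meta["batch"] == b]
        g = rng.normal(0.0, config.batch_sd, n_feat) if config.batch_sd > 0 else np.zeros(n_feat)
        order = meta.loc[cols, "injection_order"].to_numpy(float)
        span = order.max() - order.min()
        rank = (order - order.min()) / span if span > 0 else np.zeros_like(order)
        mult = drift_multiplier(rank, config.drift_amplitude, config.drift_shape)
        out.intensities.loc[:, cols] = (
            out.intensities.loc[:, cols].to_numpy() * np.exp(g)[:, None] * mult[None, :]
        )
    return out
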