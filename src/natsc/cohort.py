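"""Synthetic longitudinal cohort generator.

Emulates the study design the analysis assumes: 27 mild-TBI patients and
21 matched controls at visit 1 (~3 weeks post-injury), outcome follow-up
for 20 patients at visit 2 (~16 weeks) of whom 17 also complete imaging,
and outcome-only follow-up for 15 at visit 3 (~60 weeks).  Controls
contribute a single visit.

Generative structure (per patient):

* a severity trait ``u`` and an independent recovery-speed trait ``r``;
* visit severity = visit baseline + sev_sd*u - recovery_gain(visit)*r;
* GM/WM aTSC at v1 sit below the control mean by a configured deficit (in
  control-SD units); the subject-level deviation mixes -u with independent
  noise at ``coupling`` strength, so aTSC correlates with concurrent and
  future outcomes only when coupling > 0;
* aTSC recovers linearly between v1 and v2 at a per-day rate whose
  subject-level deviation mixes r with noise at the same coupling (no
  imaging exists beyond v2, so aTSC stops there);
* RPQ items are Binomial(4, sigmoid(base + slope*severity + item offset));
  BTACT subtest z-scores decrease with severity; GOSE bins severity, with
  8 (recovered) below the first threshold.

With coupling = 0 the aTSC columns are independent of every outcome column
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .outcomes import BTACT_SUBTESTS, RPQ_ITEMS, load_btact_norms

__all__ = ["CohortDesign", "generate_cohort", "validate_cohort", "COHORT_COLUMNS"]

VISITS = ("v1", "v2", "v3")

# fixed per-item log-odds offsets: some symptoms are commoner than others
_ITEM_OFFSETS = np.array(
    [0.5, 0.0, -0.6, -0.1, 0.2, 0.4, 0.1, -0.3, 0.2, 0.4, 0.5, 0.1, -0.5, -0.2, -0.9, -0.1]
)


@dataclass(frozen=True)
class CohortDesign:
    """Knobs of the synthetic cohort; defaults mirror the study conditions."""

    n_patients: int = 27
    n_controls: int = 21
    n_v2_outcomes: int = 20
    n_v2_imaging: int = 17
    n_v3_outcomes: int = 15

    gm_control_mean: float = 35.0
    gm_control_sd: float = 1.8
    wm_control_mean: float = 30.0
    wm_control_sd: float = 1.8
    gm_deficit_sd: float = 2.0    # v1 patient deficit in control-SD units
    wm_deficit_sd: float = 0.6
    gm_rate_mean: float = 0.04    # mM/day recovery v1 -> v2
    gm_rate_sd: float = 0.04
    wm_rate_mean: float = 0.01
    wm_rate_sd: float = 0.03

    coupling: float = 0.5         # aTSC <-> outcome correlation strength in [0, 1]

    sev_sd: float = 1.0
    sev_baseline: tuple[float, float, float] = (0.0, -0.6, -0.9)
    recovery_gain: tuple[float, float, float] = (0.0, 0.8, 1.1)
    sev_visit_noise: float = 0.3
    control_sev_mean: float = -1.6
    control_sev_sd: float = 0.7

    rpq_logit_base: float = -0.7
    rpq_logit_slope: float = 0.9
    btact_v1_mean: float = -0.35
    btact_sev_slope: float = 0.55
    btact_subtest_noise: float = 0.6
    gose_thresholds: tuple[float, float, float] = (-0.55, 0.45, 1.6)  # 8 | 7 | 6 | 5

    days_v1: tuple[float, float, float, float] = (22.0, 10.0, 5.0, 53.0)    # mean, sd, lo, hi
    days_v2: tuple[float, float, float, float] = (112.0, 21.0, 77.0, 140.0)
    days_v3: tuple[float, float, float, float] = (420.0, 49.0, 350.0, 504.0)

    nvv_mean: float = 0.0099      # normalized ventricular volume
    nvv_sd: float = 0.0045
    etiv_mean: float = 1.5e6      # mm^3
    etiv_sd: float = 1.5e5

    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_patients >= self.n_v2_outcomes >= self.n_v3_outcomes >= 0):
            raise ValueError("attrition must be nested: n_patients >= v2 >= v3")
        if self.n_v2_imaging > self.n_v2_outcomes:
            raise ValueError("imaging subjects at v2 must be v2 returnees")
        for name in ("gm_control_sd", "wm_control_sd", "gm_rate_sd", "wm_rate_sd",
                     "sev_sd", "sev_visit_noise", "control_sev_sd",
                     "btact_subtest_noise", "nvv_sd", "etiv_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")


COHORT_COLUMNS = (
    ["subject_id", "group", "visit", "days_from_injury", "atsc_gm", "atsc_wm"]
    + [f"rpq_{name}" for name in RPQ_ITEMS]
    + [f"btact_{name}" for name in BTACT_SUBTESTS]
    + ["gose", "ventricle_volume_mm3", "etiv_mm3"]
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _clipped_days(rng, spec, size):
    mean, sd, lo, hi = spec
    return np.clip(np.round(rng.normal(mean, sd, size)), lo, hi)


def _mix(rng, latent, strength, size):
    """strength*latent + sqrt(1-strength^2)*noise: unit variance preserved."""
    return strength * latent + np.sqrt(1.0 - strength**2) * rng.normal(0.0, 1.0, size)


def generate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Long-format subject x visit table; deterministic given the design."""
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    d = design
    norms = load_btact_norms()
    rows: list[dict] = []

    # ---- patients -------------------------------------------------------
    np_, rho = d.n_patients, d.coupling
    u = rng.normal(0.0, 1.0, np_)          # severity trait
    r = rng.normal(0.0, 1.0, np_)          # recovery-speed trait

    gm_v1 = (
        d.gm_control_mean
        - d.gm_deficit_sd * d.gm_control_sd
        + d.gm_control_sd * _mix(rng, -u, rho, np_)
    )
    wm_v1 = (
        d.wm_control_mean
        - d.wm_deficit_sd * d.wm_control_sd
        + d.wm_control_sd * _mix(rng, -u, rho, np_)
    )
    gm_rate = d.gm_rate_mean + d.gm_rate_sd * _mix(rng, r, rho, np_)
    wm_rate = d.wm_rate_mean + d.wm_rate_sd * _mix(rng, r, rho, np_)

    days1 = _clipped_days(rng, d.days_v1, np_)
    days2 = np.maximum(_clipped_days(rng, d.days_v2, np_), days1 + 1)
    days3 = np.maximum(_clipped_days(rng, d.days_v3, np_), days2 + 1)

    ids = np.arange(np_)
    v2_ids = rng.choice(ids, size=d.n_v2_outcomes, replace=False)
    v2_imaging = rng.choice(np.sort(v2_ids), size=d.n_v2_imaging, replace=False)
    v3_ids = rng.choice(np.sort(v2_ids), size=d.n_v3_outcomes, replace=False)
    v2_set, v2_img_set, v3_set = set(v2_ids), set(v2_imaging), set(v3_ids)

    etiv = rng.normal(d.etiv_mean, d.etiv_sd, np_ + d.n_controls)
    nvv = np.clip(
        rng.normal(d.nvv_mean, d.nvv_sd, np_ + d.n_controls), 0.001, None
    )

    for i in range(np_):
        visits = ["v1"] + (["v2"] if i in v2_set else []) + (["v3"] if i in v3_set else [])
        days = {"v1": days1[i], "v2": days2[i], "v3": days3[i]}
        for v in visits:
            vi = VISITS.index(v)
            sev = (
                d.sev_baseline[vi]
                + d.sev_sd * u[i]
                - d.recovery_gain[vi] * r[i]
                + rng.normal(0.0, d.sev_visit_noise)
            )
            p_items = _sigmoid(d.rpq_logit_base + d.rpq_logit_slope * sev + _ITEM_OFFSETS)
            rpq = rng.binomial(4, p_items)
            z_sub = (
                d.btact_v1_mean
                - d.btact_sev_slope * (sev - d.sev_baseline[0])
                + rng.normal(0.0, d.btact_subtest_noise, len(BTACT_SUBTESTS))
            )
            gose = 8 - int(np.searchsorted(d.gose_thresholds, sev, side="right"))
            gose = max(3, min(8, gose))

            if v == "v1":
                atsc_gm, atsc_wm = gm_v1[i], wm_v1[i]
            elif v == "v2" and i in v2_img_set:
                dt = days[v] - days["v1"]
                atsc_gm = gm_v1[i] + gm_rate[i] * dt
                atsc_wm = wm_v1[i] + wm_rate[i] * dt
            else:
                atsc_gm = atsc_wm = np.nan

            row = {
                "subject_id": f"p{i:03d}",
                "group": "patient",
                "visit": v,
                "days_from_injury": days[v],
                "atsc_gm": atsc_gm,
                "atsc_wm": atsc_wm,
                "gose": gose,
                "ventricle_volume_mm3": nvv[i] * etiv[i],
                "etiv_mm3": etiv[i],
            }
            row.update({f"rpq_{name}": int(s) for name, s in zip(RPQ_ITEMS, rpq)})
            row.update(
                {
                    f"btact_{name}": norms[name]["mean"] + norms[name]["sd"] * z
                    for name, z in zip(BTACT_SUBTESTS, z_sub)
                }
            )
            rows.append(row)

    # ---- controls -------------------------------------------------------
    for j in range(d.n_controls):
        sev = rng.normal(d.control_sev_mean, d.control_sev_sd)
        p_items = _sigmoid(d.rpq_logit_base + d.rpq_logit_slope * sev + _ITEM_OFFSETS)
        rpq = rng.binomial(4, p_items)
        z_sub = (
            -d.btact_sev_slope * (sev - d.control_sev_mean)
            + rng.normal(0.0, d.btact_subtest_noise, len(BTACT_SUBTESTS))
        )
        k = np_ + j
        row = {
            "subject_id": f"c{j:03d}",
            "group": "control",
            "visit": "v1",
            "days_from_injury": np.nan,
            "atsc_gm": rng.normal(d.gm_control_mean, d.gm_control_sd),
            "atsc_wm": rng.normal(d.wm_control_mean, d.wm_control_sd),
            "gose": np.nan,
            "ventricle_volume_mm3": nvv[k] * etiv[k],
            "etiv_mm3": etiv[k],
        }
        row.update({f"rpq_{name}": int(s) for name, s in zip(RPQ_ITEMS, rpq)})
        row.update(
            {
                f"btact_{name}": norms[name]["mean"] + norms[name]["sd"] * z
                for name, z in zip(BTACT_SUBTESTS, z_sub)
            }
        )
        rows.append(row)

    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    validate_cohort(df)
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    """Schema and invariant checks; raises with the offending fields."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if df.duplicated(["subject_id", "visit"]).any():
        raise ValueError("duplicate (subject_id, visit) rows")
    if not set(df["visit"]).issubset(set(VISITS)):
        raise ValueError("visit labels must be v1/v2/v3")
    if not set(df["group"]).issubset({"patient", "control"}):
        raise ValueError("group labels must be patient/control")

    patients = df[df["group"] == "patient"]
    for sid, sub in patients.groupby("subject_id"):
        if "v1" not in set(sub["visit"]):
            raise ValueError(f"patient {sid} lacks a v1 row")
        days = sub.sort_values("visit")["days_from_injury"].to_numpy()
        if np.any(np.diff(days) <= 0):
            raise ValueError(f"patient {sid} visit days do not strictly increase")

    rpq_cols = [f"rpq_{name}" for name in RPQ_ITEMS]
    rpq = df[rpq_cols].to_numpy()
    if np.nanmin(rpq) < 0 or np.nanmax(rpq) > 4:
        raise ValueError("RPQ items outside 0-4")
    gose = patients["gose"].dropna()
    if len(gose) and (gose.min() < 3 or gose.max() > 8):
        raise ValueError("GOSE outside 3-8")
    if (df["etiv_mm3"] <= 0).any():
        raise ValueError("eTIV must be positive")
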