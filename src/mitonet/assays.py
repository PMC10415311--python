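"""Raw assay readouts -> QC'd mitochondrial features and behavioral composites.

Covers spectrophotometric enzyme activities (CS, CI, CII, CIV), qPCR-derived
mtDNA measures, the composite mitochondrial health index (MHI), behavioral
composite scores, and standardized effect sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: replicate coefficient-of-variation cutoff for duplicate enzyme assays
ACTIVITY_CV_CUTOFF = 0.10
#: Ct exclusion threshold: amplicons with mean Ct above this are unreliable
CT_EXCLUSION = 33.0
#: triplicate CV above which the farthest-from-median replicate is dropped
CT_TRIPLICATE_CV = 0.02
#: final CV above which the qPCR sample is discarded
CT_FINAL_CV = 0.10

#: sign convention per behavioral test: which raw measures are multiplied by
#: -1 before averaging, so that higher composite = more avoidant/anxious.
BEHAVIOR_SIGN_FLIPS = {
    "SI": ("si_ratio", "si_zone_time"),
    "OFT": ("center_time_pct", "center_distance_pct"),
    "EPM": ("open_arm_time_pct",),
    "NSF": (),
}

NSF_CAP_SECONDS = 600.0


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class ActivityRecord:
    """One enzymatic-activity measurement (replicate absorbance slopes)."""

    sample_id: str
    assay: str
    replicate_slopes: list[float]
    nonspecific_slope: float
    plate_id: str = "plate1"
    extinction_dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.assay not in ("CS", "CI", "CII", "CIV"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.extinction_dilution_factor <= 0:
            raise ValueError("extinction_dilution_factor must be positive")


@dataclass
class QpcrRecord:
    """Triplicate Ct values for the mtDNA (COX1) and nDNA (B2M) amplicons."""

    sample_id: str
    mt_cts: list[float]
    n_cts: list[float]
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        for ct in list(self.mt_cts) + list(self.n_cts):
            if not np.isnan(ct) and ct <= 0:
                raise ValueError("Ct values must be positive")


@dataclass
class ActivityResult:
    sample_id: str
    assay: str
    value: float | None
    cv: float | None
    flagged: bool
    reason: str | None = None


@dataclass
class QpcrResult:
    sample_id: str
    mtdnacn: float
    delta_ct: float
    qc_code: str = "ok"
    dropped_replicates: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.qc_code == "ok"


@dataclass
class HedgesG:
    g: float
    ci_low: float
    ci_high: float
    significant: bool
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# enzyme activities
# ---------------------------------------------------------------------------

def specific_activity(record: ActivityRecord) -> ActivityResult:
    """Specific activity = (mean replicate slope - non-specific slope) x factor.

    The replicate CV is checked against the 10% duplicate cutoff; samples
    exceeding it are flagged (and treated as excluded downstream).
    """
    slopes = np.asarray(
        [s for s in record.replicate_slopes if s is not None and not np.isnan(s)],
        dtype=float,
    )
    if slopes.size == 0:
        log.warning("sample %s assay %s: all replicates missing",
                    record.sample_id, record.assay)
        return ActivityResult(record.sample_id, record.assay, None, None,
                              flagged=True, reason="no_replicates")
    mean = slopes.mean()
    cv = None
    flagged = False
    reason = None
    if slopes.size >= 2 and mean != 0:
        cv = float(slopes.std(ddof=1) / abs(mean))
        if cv > ACTIVITY_CV_CUTOFF:
            flagged = True
            reason = "replicate_cv_gt_0.10"
    value = (mean - record.nonspecific_slope) * record.extinction_dilution_factor
    return ActivityResult(record.sample_id, record.assay, float(value), cv,
                          flagged=flagged, reason=reason)


def normalize_plate(
    activities: dict[str, np.ndarray | list[float]],
    positive_controls: dict[str, float],
    assay_reference: float,
) -> dict[str, np.ndarray]:
    """Normalize per-plate activities to the assay-wide positive-control level.

    Each plate's activities are multiplied by ``assay_reference / control`` so
    that a plate whose positive control sits at the assay mean is unchanged
    (factor 1).  Plates with a nonpositive control are excluded.
    """
    out: dict[str, np.ndarray] = {}
    for plate_id, values in activities.items():
        control = positive_controls.get(plate_id)
        if control is None or not np.isfinite(control) or control <= 0:
            log.warning("plate %s excluded: invalid positive control %r",
                        plate_id, control)
            continue
        factor = assay_reference / control
        out[plate_id] = np.asarray(values, dtype=float) * factor
    return out


# ---------------------------------------------------------------------------
# qPCR: mtDNAcn and mtDNA density
# ---------------------------------------------------------------------------

def _triplicate_qc(cts: np.ndarray) -> tuple[np.ndarray, bool]:
    """Drop the replicate farthest from the median if triplicate CV > 0.02.

    Returns (retained values, whether a replicate was dropped).
    """
    cts = cts[~np.isnan(cts)]
    if cts.size < 2:
        return cts, False
    cv = cts.std(ddof=1) / cts.mean()
    if cv > CT_TRIPLICATE_CV and cts.size >= 3:
        dist = np.abs(cts - np.median(cts))
        keep = np.delete(cts, int(np.argmax(dist)))
        return keep, True
    return cts, False


def ct_to_mtdnacn(record: QpcrRecord) -> QpcrResult:
    """mtDNAcn = 2^(dCt) x 2 with dCt = mean(nDNA Ct) - mean(mtDNA Ct).

    QC order: (1) mean Ct > 33 excludes the sample; (2) triplicate CV > 0.02
    drops the outlier replicate; (3) remaining CV > 0.1 discards the sample.
    """
    mt = np.asarray(record.mt_cts, dtype=float)
    n = np.asarray(record.n_cts, dtype=float)
    mt = mt[~np.isnan(mt)]
    n = n[~np.isnan(n)]
    if mt.size == 0 or n.size == 0:
        return QpcrResult(record.sample_id, np.nan, np.nan, qc_code="missing_cts")
    if mt.mean() > CT_EXCLUSION or n.mean() > CT_EXCLUSION:
        return QpcrResult(record.sample_id, np.nan, np.nan, qc_code="ct_gt_33")
    dropped: dict[str, bool] = {}
    mt, dropped["mt"] = _triplicate_qc(mt)
    n, dropped["n"] = _triplicate_qc(n)
    for name, cts in (("mt", mt), ("n", n)):
        if cts.size >= 2 and cts.std(ddof=1) / cts.mean() > CT_FINAL_CV:
            return QpcrResult(record.sample_id, np.nan, np.nan,
                              qc_code=f"{name}_cv_gt_0.10", dropped_replicates=dropped)
    delta_ct = float(n.mean() - mt.mean())
    return QpcrResult(record.sample_id, 2.0 ** delta_ct * 2.0, delta_ct,
                      dropped_replicates=dropped)


def ct_to_mtdna_density(mt_ct: float, mode: str = "verbatim") -> tuple[float, str]:
    """Linearize a mean mtDNA Ct into a relative per-volume abundance.

    ``verbatim`` mode returns 2^Ct x 1e-12 exactly as published, even though
    this increases with Ct; ``corrected`` returns 2^(-Ct) x 1e12, the
    sign-corrected convention where lower Ct means more template.  The mode
    used is returned alongside the value so it lands in output metadata.
    """
    if mode == "verbatim":
        return float(2.0 ** mt_ct * 1e-12), mode
    if mode == "corrected":
        return float(2.0 ** (-mt_ct) * 1e12), mode
    raise ValueError(f"unknown linearization mode {mode!r}")


# ---------------------------------------------------------------------------
# MHI
# ---------------------------------------------------------------------------

def compute_mhi(features: pd.DataFrame) -> pd.Series:
    """Mitochondrial health index per animal for one site.

    ``features``: animals x [CI, CII, CIV, CS, mtdna_density].  Each feature
    is divided by its across-animal mean (centered to 1), then
    MHI = (CI + CII + CIV) / (CS + mtdna_density + 1) x 100, so an animal at
    the mean of all five features scores exactly 100.
    """
    cols = ["CI", "CII", "CIV", "CS", "mtdna_density"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"missing MHI input features: {missing}")
    x = features[cols].astype(float)
    complete = x.dropna()
    if len(complete) < 2:
        raise ValueError("need >=2 animals with complete 5-feature vectors")
    means = x.mean(axis=0, skipna=True)
    if (means == 0).any() or means.isna().any():
        bad = means.index[(means == 0) | means.isna()].tolist()
        log.warning("site skipped: zero/undefined feature mean for %s", bad)
        return pd.Series(np.nan, index=features.index, name="MHI")
    c = x / means
    mhi = (c["CI"] + c["CII"] + c["CIV"]) / (c["CS"] + c["mtdna_density"] + 1.0) * 100.0
    mhi.name = "MHI"
    return mhi


# ---------------------------------------------------------------------------
# behavior composites
# ---------------------------------------------------------------------------

def behavior_zscore(raw: pd.DataFrame, test: str) -> pd.Series:
    """Composite avoidance score for one behavioral test.

    ``raw``: animals x raw measures.  Each measure is z-scored across
    animals, sign-flipped per the test's convention (so higher always means
    more avoidant), and measures are averaged per animal.  NSF latencies are
    capped at 600 s before scoring.
    """
    if test not in BEHAVIOR_SIGN_FLIPS:
        raise ValueError(f"unknown behavioral test {test!r}")
    if raw.dropna(how="all").shape[0] < 3:
        raise ValueError("need >=3 animals for behavioral z-scores")
    x = raw.astype(float).copy()
    if test == "NSF":
        x = x.clip(upper=NSF_CAP_SECONDS)
    z = (x - x.mean(axis=0, skipna=True)) / x.std(axis=0, ddof=1, skipna=True)
    for col in BEHAVIOR_SIGN_FLIPS[test]:
        if col in z.columns:
            z[col] = -z[col]
    composite = z.mean(axis=1, skipna=True)
    composite.name = test
    return composite


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def hedges_g(group_a, group_b, alpha: float = 0.05) -> HedgesG:
    """Small-sample-corrected standardized mean difference (a - b) with CI."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need >=2 observations per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        log.warning("hedges_g undefined: zero pooled variance")
        return HedgesG(np.nan, np.nan, np.nan, significant=False, n_a=na, n_b=nb)
    d = (a.mean() - b.mean()) / math.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    var_d = (na + nb) / (na * nb) + d * d / (2.0 * (na + nb))
    se_g = j * math.sqrt(var_d)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = g - zcrit * se_g, g + zcrit * se_g
    return HedgesG(g, lo, hi, significant=bool(lo > 0 or hi < 0), n_a=na, n_b=nb)


# ---------------------------------------------------------------------------
# punch-mass estimate
# ---------------------------------------------------------------------------

def punch_mass_mg(
    diameter_mm: float = 1.0,
    height_um: float = 200.0,
    density_g_cm3: float = 1.04,
    n_punches: int = 1,
) -> float:
    """Estimated tissue mass (mg) of cylindrical biopsy punches.

    m = density x pi r^2 h; punches are too light to weigh directly, so mass
    is estimated from cylinder volume and brain tissue density.
    """
    r_cm = diameter_mm / 2.0 / 10.0
    h_cm = height_um * 1e-4
    volume_cm3 = math.pi * r_cm ** 2 * h_cm
    return volume_cm3 * density_g_cm3 * 1000.0 * n_punches
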