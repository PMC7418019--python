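"""Synthetic quarterly duplicative-prescription panels with known truth.

No public accession exists for the quarterly indicator panels the national
insurer publishes, so every pipeline stage is exercised against generated
panels whose ground truth is known. A hospital is a trend profile
(improving / stable / worsening) around its type's management threshold:

    rate_t = max(0, base_rate + slope * t + Normal(0, noise_sd))

with the per-type base rates defaulting to the published tolerance
thresholds (medical center 0.5805%, regional 0.4273%, district 0.5934%).
District hospitals receive the highest quarter-level missingness, mirroring
the incomplete reporting observed for that stratum. All generators are
deterministic for a fixed seed and never touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import HOSPITAL_TYPES, REGIONS, Hospital, IndicatorPanel

#: published management thresholds (%) used as default base rates
BASE_RATES = {"medical_center": 0.5805, "regional": 0.4273, "district": 0.5934}

#: hospital-type mix of the antihypertension panel (medical center /
#: regional / district); district dominance keeps contingency margins realistic
DEFAULT_N_PER_TYPE = {"medical_center": 20, "regional": 77, "district": 305}

#: per-type regional mix (fractions over the six regions, Taipei..East)
REGION_MIX = {
    "medical_center": (0.35, 0.10, 0.20, 0.15, 0.15, 0.05),
    "regional": (0.14, 0.22, 0.22, 0.18, 0.20, 0.04),
    "district": (0.10, 0.20, 0.28, 0.13, 0.25, 0.04),
}

#: per-type trend-profile mix (improving, stable, worsening): higher-level
#: hospitals improve more often, matching their better published rankings
DEFAULT_PROFILE_MIX = {
    "medical_center": {"improving": 0.80, "stable": 0.15, "worsening": 0.05},
    "regional": {"improving": 0.70, "stable": 0.20, "worsening": 0.10},
    "district": {"improving": 0.30, "stable": 0.40, "worsening": 0.30},
}

#: quarter-level missingness by type; district reporting is the patchiest
DEFAULT_MISSING_RATE = {"medical_center": 0.0, "regional": 0.02, "district": 0.08}

DEFAULT_SLOPE = 0.01  # percent per quarter
DEFAULT_NOISE_SD = 0.05  # percent

#: per-region (lat_lo, lat_hi, lon_lo, lon_hi) boxes inside Taiwan's extent
REGION_BOXES = {
    "Taipei": (24.95, 25.20, 121.40, 121.70),
    "North": (24.50, 25.10, 120.90, 121.40),
    "Central": (23.90, 24.50, 120.40, 121.00),
    "South": (22.95, 23.90, 120.10, 120.60),
    "Kao-Pin": (22.00, 22.95, 120.20, 120.80),
    "East": (22.80, 24.30, 121.00, 121.70),
}

NATIONAL_BOX = (21.9, 25.3, 120.0, 122.0)


@dataclass(frozen=True)
class TrendProfile:
    """Generating trend of one hospital; slope sign encodes the label."""

    label: str
    base_rate: float
    slope: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")
        if self.label == "improving" and not self.slope < 0:
            raise ValueError("improving requires slope < 0")
        if self.label == "worsening" and not self.slope > 0:
            raise ValueError("worsening requires slope > 0")
        if self.label == "stable" and self.slope != 0:
            raise ValueError("stable requires slope = 0")
        if self.label not in ("improving", "stable", "worsening"):
            raise ValueError(f"unknown trend label {self.label!r}")

    @property
    def expected_quadrant(self) -> str:
        """Quadrant under zero noise: positive slope is rising duplication
        (quadrant I); zero or negative slope with a positive level is IV."""
        return "I" if self.slope > 0 else "IV"


@dataclass
class SyntheticTruth:
    """hospital_id -> (TrendProfile, htype, region, expected_quadrant)."""

    profiles: dict[str, TrendProfile]
    htypes: dict[str, str]
    regions: dict[str, str]

    def expected_quadrant(self, hospital_id: str) -> str:
        return self.profiles[hospital_id].expected_quadrant

    def label(self, hospital_id: str) -> str:
        return self.profiles[hospital_id].label


def generate_coordinates(region: str, rng) -> tuple[float, float]:
    """Uniform (lat, lon) draw within the region's bounding box."""
    if region not in REGION_BOXES:
        raise ValueError(f"unknown region {region!r}")
    lat_lo, lat_hi, lon_lo, lon_hi = REGION_BOXES[region]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return float(rng.uniform(lat_lo, lat_hi)), float(rng.uniform(lon_lo, lon_hi))


def _quarter_labels(n_quarters: int, start: str = "2010Q3") -> list[str]:
    start_p = pd.Period(start, freq="Q")
    return [str(start_p + i) for i in range(n_quarters)]


def generate_panel(
    n_per_type: dict | None = None,
    quarters: int = 25,
    profiles: dict | None = None,
    missing_rate: dict | None = None,
    seed: int = 0,
    drug: str = "antihypertension",
    base_rates: dict | None = None,
    slope: float = DEFAULT_SLOPE,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> tuple[IndicatorPanel, SyntheticTruth]:
    """Generate a quarterly panel plus its ground truth.

    Parameters
    ----------
    n_per_type : dict htype -> count
        Defaults to the 20/77/305 medical-center/regional/district mix.
    quarters : int
        Number of fiscal quarters (default 25, starting 2010Q3).
    profiles : dict htype -> {label: probability}
        Trend-profile mix per hospital type.
    missing_rate : dict htype -> probability
        Per-quarter missingness; district hospitals default to the highest.
    seed : int
        Seeds an isolated ``numpy.random.default_rng``; runs are bit-identical.
    slope, noise_sd : float
        Magnitude of the linear trend (% per quarter) and the Gaussian
        quarter noise SD (%). Rates are floored at zero.
    """
    n_per_type = dict(DEFAULT_N_PER_TYPE if n_per_type is None else n_per_type)
    profiles = dict(DEFAULT_PROFILE_MIX if profiles is None else profiles)
    missing_rate = dict(DEFAULT_MISSING_RATE if missing_rate is None else missing_rate)
    base_rates = dict(BASE_RATES if base_rates is None else base_rates)
    rng = np.random.default_rng(seed)

    hospitals: list[Hospital] = []
    truth_profiles: dict[str, TrendProfile] = {}
    truth_htypes: dict[str, str] = {}
    truth_regions: dict[str, str] = {}
    rows = []
    labels = _quarter_labels(quarters)
    t = np.arange(quarters, dtype=float)

    serial = 0
    for htype in HOSPITAL_TYPES:
        count = int(n_per_type.get(htype, 0))
        if count < 0:
            raise ValueError("counts must be >= 0")
        if count == 0:
            continue
        mix = profiles.get(htype, profiles) if isinstance(
            next(iter(profiles.values())), dict
        ) else profiles
        mix_labels = list(mix)
        mix_p = np.array([mix[k] for k in mix_labels], dtype=float)
        mix_p = mix_p / mix_p.sum()
        p_miss = float(missing_rate.get(htype, 0.0))
        if not 0.0 <= p_miss <= 1.0:
            raise ValueError("missing_rate probabilities must be in [0, 1]")
        for _ in range(count):
            serial += 1
            hid = f"H{serial:04d}"
            region = REGIONS[int(rng.choice(len(REGIONS), p=REGION_MIX[htype]))]
            lat, lon = generate_coordinates(region, rng)
            label = mix_labels[int(rng.choice(len(mix_labels), p=mix_p))]
            sl = {"improving": -slope, "stable": 0.0, "worsening": slope}[label]
            profile = TrendProfile(
                label=label, base_rate=base_rates[htype], slope=sl, noise_sd=noise_sd
            )
            series = np.maximum(
                0.0,
                profile.base_rate + profile.slope * t + rng.normal(0.0, noise_sd, quarters),
            )
            if p_miss > 0:
                mask = rng.random(quarters) < p_miss
                series = series.astype(float)
                series[mask] = np.nan
            hospitals.append(
                Hospital(
                    id=hid, name=f"Hospital {serial}", htype=htype, region=region,
                    lat=lat, lon=lon,
                )
            )
            truth_profiles[hid] = profile
            truth_htypes[hid] = htype
            truth_regions[hid] = region
            rows.append(series)

    rates = pd.DataFrame(
        np.asarray(rows, dtype=float) if rows else np.empty((0, quarters)),
        index=pd.Index([h.id for h in hospitals], name="id"),
        columns=labels,
    )
    panel = IndicatorPanel(drug=drug, hospitals=hospitals, rates=rates)
    truth = SyntheticTruth(
        profiles=truth_profiles, htypes=truth_htypes, regions=truth_regions
    )
    return panel, truth


def one_factor_panel(
    n_hospitals: int, n_quarters: int, loading: float, seed: int = 0
) -> np.ndarray:
    """Standardized cases x items matrix from a one-factor model.

    item_t = loading * factor + sqrt(1 - loading^2) * noise, columns
    z-scored afterwards; loading=1 yields perfectly correlated columns.
    """
    if not 0.0 <= loading <= 1.0:
        raise ValueError("loading must be in [0, 1]")
    rng = np.random.default_rng(seed)
    factor = rng.normal(size=(n_hospitals, 1))
    noise = rng.normal(size=(n_hospitals, n_quarters))
    x = loading * factor + np.sqrt(1.0 - loading**2) * noise
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd
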