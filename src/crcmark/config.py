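"""Cohort configuration for the synthetic surveillance study generator.

The defaults describe a cohort of 85 colorectal-cancer patients (57 radical,
28 palliative resections) with one preoperative sample (a day before surgery),
one postoperative sample (5-10 days after) and 0-7 irregular follow-up samples
per patient.  Marker levels are lognormal; their location defaults are anchored
to typical median plasma values for the six markers carried through the whole
analysis (four miRNAs as 2^-dCt relative values, CEA in ng/mL, CA19-9 in U/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from crcmark.errors import ConfigError

SERUM_MARKERS = ("CEA", "CA19-9")


@dataclass(frozen=True)
class MarkerSpec:
    """One marker of the panel.

    log_level_mean / log_level_sd are the natural-log location and scale of
    the preoperative level distribution.  Serum markers (CEA, CA19-9) are
    measured by immunoassay and bypass the qPCR chain entirely.
    """

    name: str
    log_level_mean: float
    log_level_sd: float = 1.2

    @property
    def is_serum(self) -> bool:
        return self.name in SERUM_MARKERS


def default_marker_panel() -> tuple[MarkerSpec, ...]:
    """Panel of the six markers used in every downstream analysis.

    Locations are ln(median preoperative level): relative 2^-dCt units for the
    miRNAs, ng/mL for CEA, U/mL for CA19-9.
    """
    return (
        MarkerSpec("miR-20a", math.log(0.247)),
        MarkerSpec("miR-21", math.log(1.050)),
        MarkerSpec("miR-23a", math.log(0.705)),
        MarkerSpec("miR-223", math.log(1.275)),
        MarkerSpec("CEA", math.log(3.1), 1.5),
        MarkerSpec("CA19-9", math.log(11.0), 1.5),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_patients, fraction_radical
        Cohort size and fraction receiving radical (complete) resection;
        the radical count is ``round(n_patients * fraction_radical)``.
    markers
        The marker panel with per-marker lognormal parameters.
    marker_correlation
        Loading (in [0, 1]) of every marker's log level on a shared
        standardized per-patient factor ("tumor burden"); 0 gives independent
        markers, 1 perfectly correlated ones.
    postop_drop_radical, postop_drop_palliative
        Multiplicative postoperative drop factors in (0, 1]; complete tumor
        removal lowers circulating levels, palliative surgery barely does.
    level_noise_sd
        Natural-log residual sd of postoperative and follow-up samples around
        the patient's remission level.
    hazard_baseline
        Death hazard (events/week) of a radical patient with average burden.
    log_hazard_per_logunit
        Proportional-hazards coefficient on the standardized burden factor.
    palliative_hazard_multiplier, palliative_burden_shift
        Palliative (residual-disease) patients die much faster and present
        with higher marker levels; these shift their hazard and burden.
    censor_horizon_weeks
        Administrative censoring horizon (default three years).
    recurrence_fraction
        Fraction of radical patients who relapse during follow-up; relapse
        multiplies all post-recurrence follow-up levels by
        ``recurrence_fold_signal``.
    followup_samples_range
        Inclusive integer range of the per-patient follow-up sample count,
        within [0, 7]; sampling times are uniform on
        ``followup_window_weeks``.
    ct_baseline, ct_noise_sd, spikein_ct_mean, spikein_ct_sd
        Raw Ct generation: a unit-level target measured with a nominal
        spike-in reads ``ct_baseline`` cycles; each halving of level adds one
        cycle; per-sample spike-in Ct is N(spikein_ct_mean, spikein_ct_sd)
        and shifts the target Ct with it (so spike-in normalization cancels
        extraction efficiency).
    n_runs, run_shift_sd
        Number of simulated PCR runs and the sd (cycles) of per-run,
        per-marker plate shifts, expressed relative to the first run.
    """

    n_patients: int = 85
    fraction_radical: float = 57 / 85
    markers: tuple[MarkerSpec, ...] = field(default_factory=default_marker_panel)
    marker_correlation: float = 0.6
    postop_drop_radical: float = 0.5
    postop_drop_palliative: float = 0.9
    level_noise_sd: float = 0.3
    hazard_baseline: float = 0.001
    log_hazard_per_logunit: float = 0.7
    palliative_hazard_multiplier: float = 8.0
    palliative_burden_shift: float = 0.5
    censor_horizon_weeks: float = 156.0
    recurrence_fraction: float = 9 / 31
    recurrence_fold_signal: float = 3.0
    followup_samples_range: tuple[int, int] = (0, 7)
    followup_window_weeks: tuple[float, float] = (2.0, 120.0)
    ct_baseline: float = 26.0
    ct_noise_sd: float = 0.15
    spikein_ct_mean: float = 26.0
    spikein_ct_sd: float = 0.5
    n_runs: int = 4
    run_shift_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ("fraction_radical", "recurrence_fraction", "marker_correlation"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a finite proportion in [0, 1], got {v}")
        for name in (
            "level_noise_sd",
            "ct_noise_sd",
            "spikein_ct_sd",
            "run_shift_sd",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0.0):
                raise ConfigError(f"{name} must be a finite sd >= 0, got {v}")
        for name in ("postop_drop_radical", "postop_drop_palliative"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 < v <= 1.0):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        for name in (
            "hazard_baseline",
            "recurrence_fold_signal",
            "palliative_hazard_multiplier",
            "censor_horizon_weeks",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0.0):
                raise ConfigError(f"{name} must be finite and > 0, got {v}")
        if not math.isfinite(self.log_hazard_per_logunit):
            raise ConfigError("log_hazard_per_logunit must be finite")
        if not math.isfinite(self.palliative_burden_shift):
            raise ConfigError("palliative_burden_shift must be finite")
        lo, hi = self.followup_samples_range
        if not (isinstance(lo, int) and isinstance(hi, int) and 0 <= lo <= hi <= 7):
            raise ConfigError(
                f"followup_samples_range must be integers with 0 <= lo <= hi <= 7, got {self.followup_samples_range}"
            )
        wlo, whi = self.followup_window_weeks
        if not (math.isfinite(wlo) and math.isfinite(whi) and 0 < wlo < whi):
            raise ConfigError("followup_window_weeks must satisfy 0 < lo < hi")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if not self.markers:
            raise ConfigError("marker panel must not be empty")
        for m in self.markers:
            if not (math.isfinite(m.log_level_mean) and math.isfinite(m.log_level_sd) and m.log_level_sd >= 0):
                raise ConfigError(f"marker {m.name}: non-finite or negative lognormal parameters")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate marker names in panel")

    # convenience accessors -------------------------------------------------
    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def mirna_markers(self) -> list[MarkerSpec]:
        """Markers quantified by qPCR (everything that is not a serum assay)."""
        return [m for m in self.markers if not m.is_serum]

    @property
    def serum_markers(self) -> list[MarkerSpec]:
        return [m for m in self.markers if m.is_serum]

    def with_(self, **kwargs) -> "CohortConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)
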