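"""Synthetic study generator: every input the pipeline consumes, with known
ground truth.

The generator emulates the measurement structure of an ex vivo glycan
fermentation screen: 96-well kinetic plates (OD600 growth plus dual-channel
BCECF fluorescence and headspace gas pressure) for glycans drawn from a small
set of fermentation-dynamic archetypes, pH standard-curve plates, replicate
fecal-culture relative-abundance tables across donors with glycan-specific
planted genus effects conserved across donors, SCFA peak-area tables with a
linear detector response and internal standards, and survival / body-weight
records for intervention comparisons.

Every output is a deterministic function of a single integer seed, ground
truth (archetype label per glycan, planted log2 effects, true calibration
parameters) is returned alongside the data, and all noise terms vanish in the
noise->0 limit so closed-form checks stay exact.

Growth is 4-parameter logistic OD(t) = OD0 + K / (1 + exp(-r (t - tm)));
acidification is a falling logistic from ph_start to ph_floor plus an
optional linear rebound ramp; fluorescence channels are produced by pushing
the true pH through a known 4PL ratio model.  Defaults: cultures sampled
every 0.5 h for 45 h, triplicate, additive OD noise SD 0.01, 1 percent
relative fluorescence noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ph import PhCalibrationModel, fit_4pl

__all__ = [
    "GrowthArchetype",
    "SimConfig",
    "DEFAULT_ARCHETYPES",
    "TRUE_PH_MODEL",
    "generate_plate_timeseries",
    "generate_ph_standards",
    "generate_taxa_tables",
    "generate_scfa_peaks",
    "generate_survival_weights",
]


@dataclass(frozen=True)
class GrowthArchetype:
    """One fermentation-dynamics archetype (shape of growth + pH curves).

    ``carrying_capacity`` (OD600) and ``rate`` (1/h) with logistic midpoint
    ``midpoint`` (h) and baseline ``od0``; acidification runs from
    ``ph_start`` down to ``ph_floor`` with maximum rate
    ``acidification_rate`` (pH/h), optionally followed by a linear
    ``rebound`` (pH units recovered by the end of the run).
    """

    name: str
    carrying_capacity: float
    rate: float
    midpoint: float
    od0: float = 0.05
    ph_start: float = 6.8
    ph_floor: float = 5.0
    acidification_rate: float = 0.3
    rebound: float = 0.0
    compound_class: str = "SG"
    gas_capacity_psi: float = 0.0  # 0 => scaled from carrying_capacity

    def __post_init__(self) -> None:
        if self.carrying_capacity <= 0:
            raise ValueError(f"archetype {self.name!r}: carrying_capacity must be > 0")
        if self.rate <= 0:
            raise ValueError(f"archetype {self.name!r}: rate must be > 0")
        if self.ph_start <= self.ph_floor:
            raise ValueError(f"archetype {self.name!r}: ph_start must exceed ph_floor")

    def od_curve(self, t: np.ndarray) -> np.ndarray:
        return self.od0 + self.carrying_capacity / (
            1.0 + np.exp(-self.rate * (t - self.midpoint))
        )

    def ph_curve(self, t: np.ndarray) -> np.ndarray:
        span = self.ph_start - self.ph_floor
        a = 4.0 * self.acidification_rate / span
        t_ph = self.midpoint + 1.0  # acidification trails growth slightly
        ph = self.ph_floor + span / (1.0 + np.exp(a * (t - t_ph)))
        if self.rebound and t[-1] > t_ph:
            ramp = np.clip((t - t_ph) / (t[-1] - t_ph), 0.0, 1.0)
            ph = ph + self.rebound * ramp
        return ph

    def pressure_curve(self, t: np.ndarray) -> np.ndarray:
        cap = self.gas_capacity_psi or 10.0 * self.carrying_capacity
        return cap / (1.0 + np.exp(-self.rate * (t - self.midpoint)))


# Five archetypes mirroring the canonical fermentation groups: fast reference
# fermenters with a precipitous pH drop, moderate fermenters, weak fermenters,
# fast fermenters with a strong pH rebound, and slow steady synthetic-glycan
# fermenters with gradual acidification.  The five differ along several
# independent descriptor axes (growth magnitude, timing, pH depth,
# acidification rate, rebound) so that no single axis dominates the
# between-group geometry; every archetype rebounds at least slightly, which
# anchors the time-of-pH-minimum descriptor.  Documented margin: neighboring
# archetypes differ by >= 0.2 OD in carrying capacity or >= 4 h in midpoint
# and >= 0.3 pH in floor, several within-group SDs at default noise -- this
# is what lets downstream clustering recover the planted labels.
DEFAULT_ARCHETYPES = (
    GrowthArchetype("fast_acidic", 1.1, 0.9, 8.0, ph_floor=4.8,
                    acidification_rate=0.5, rebound=0.1,
                    compound_class="reference"),
    GrowthArchetype("slow_big", 1.0, 0.3, 30.0, ph_floor=5.8,
                    acidification_rate=0.12, rebound=0.4,
                    compound_class="SG"),
    GrowthArchetype("weak", 0.2, 0.25, 18.0, ph_floor=6.3,
                    acidification_rate=0.05, rebound=0.05,
                    compound_class="SG"),
    GrowthArchetype("fast_rebound", 0.5, 0.8, 10.0, ph_floor=5.2,
                    acidification_rate=0.45, rebound=0.7,
                    compound_class="reference"),
    GrowthArchetype("moderate_deep", 0.75, 0.35, 20.0, ph_floor=5.0,
                    acidification_rate=0.15, rebound=0.15,
                    compound_class="SG"),
)

# True BCECF ratio model used to synthesize fluorescence channels.
TRUE_PH_MODEL = PhCalibrationModel(r_min=0.5, r_max=3.0, ph_mid=6.8, s=1.1)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_glycans: int = 20
    group_archetypes: tuple = DEFAULT_ARCHETYPES
    n_donors: int = 10
    n_replicates: int = 3
    n_taxa: int = 40
    effect_map: dict = field(default_factory=dict)  # class -> {taxon: log2 effect}
    noise_sd_od: float = 0.01
    noise_sd_fluor: float = 0.01     # relative
    noise_sd_pressure: float = 0.05
    timepoints: tuple = tuple(np.arange(0.0, 45.0 + 1e-9, 0.5))
    ph_model: PhCalibrationModel = TRUE_PH_MODEL
    replicate_concentration: float = 500.0  # Dirichlet precision of replicates
    donor_concentration: float = 50.0       # Dirichlet precision of donor baselines
    base_profile: tuple | None = None       # None => lognormal shared profile

    def __post_init__(self) -> None:
        for name in ("noise_sd_od", "noise_sd_fluor", "noise_sd_pressure"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.n_glycans < 1:
            raise ValueError("need at least 1 glycan")


def _glycan_ids(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def generate_plate_timeseries(config: SimConfig):
    """Long-format kinetic plate table plus the planted ground truth.

    Each glycan is assigned an archetype (round-robin) and measured in
    ``n_replicates`` wells over ``timepoints``; channels are OD600, the two
    BCECF fluorescence channels (F_sens = true ratio x F_iso), and headspace
    pressure.  Returns ``(plate, truth)``: a tidy DataFrame with columns
    (sample_id, glycan_id, compound_class, replicate, time, channel, value)
    and a per-glycan truth table (glycan_id, true_group, archetype,
    compound_class).
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.timepoints, dtype=float)
    glycans = _glycan_ids(config.n_glycans)
    arch = [config.group_archetypes[i % len(config.group_archetypes)]
            for i in range(config.n_glycans)]
    f_iso_level = 10_000.0

    frames = []
    for g, a in zip(glycans, arch):
        od_true = a.od_curve(t)
        ph_true = a.ph_curve(t)
        ratio_true = config.ph_model.predict(ph_true)
        pres_true = a.pressure_curve(t)
        for rep in range(1, config.n_replicates + 1):
            od = od_true + rng.normal(0.0, config.noise_sd_od, t.size) \
                if config.noise_sd_od else od_true
            f_iso = f_iso_level * (1.0 + (rng.normal(0.0, config.noise_sd_fluor, t.size)
                                          if config.noise_sd_fluor else 0.0))
            f_sens = ratio_true * f_iso_level * (
                1.0 + (rng.normal(0.0, config.noise_sd_fluor, t.size)
                       if config.noise_sd_fluor else 0.0))
            pres = pres_true + (rng.normal(0.0, config.noise_sd_pressure, t.size)
                                if config.noise_sd_pressure else 0.0)
            sample = f"{g}_r{rep}"
            for channel, vals in (("OD600", od), ("F_sens", f_sens),
                                  ("F_iso", f_iso), ("pressure_psi", pres)):
                frames.append(pd.DataFrame({
                    "sample_id": sample, "glycan_id": g,
                    "compound_class": a.compound_class, "replicate": rep,
                    "time": t, "channel": channel, "value": vals,
                }))
    plate = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame({
        "glycan_id": glycans,
        "true_group": [config.group_archetypes.index(a) + 1 for a in arch],
        "archetype": [a.name for a in arch],
        "compound_class": [a.compound_class for a in arch],
    })
    return plate, truth


def generate_ph_standards(true_model: PhCalibrationModel, ph_levels=None,
                          noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Standard-curve plate: (pH, ratio) pairs from the true 4PL plus noise.

    Fewer than 4 distinct levels leaves the 4PL unidentifiable and raises.
    """
    if ph_levels is None:
        ph_levels = np.linspace(4.0, 9.0, 12)
    ph_levels = np.asarray(ph_levels, dtype=float)
    if np.unique(ph_levels).size < 4:
        raise ValueError("need at least 4 distinct pH levels (4PL unidentifiable)")
    rng = np.random.default_rng(seed)
    ratio = true_model.predict(ph_levels)
    if noise_sd:
        ratio = ratio + rng.normal(0.0, noise_sd, ph_levels.size)
    return pd.DataFrame({"ph": ph_levels, "ratio": ratio})


# default planted effects: a few rare genera respond to each compound class
def default_effect_map(taxa: list[str]) -> dict:
    return {
        "SG": {taxa[0]: 2.0, taxa[1]: 1.5, taxa[2]: -1.5},
        "reference": {taxa[3]: 2.0, taxa[4]: -2.0},
    }


def generate_taxa_tables(config: SimConfig, glycans=None,
                         pathogen: str | None = None,
                         pathogen_fraction: float = 0.08):
    """Replicate fecal-culture abundance tables with planted genus effects.

    ``glycans`` is a list of (glycan_id, compound_class) pairs; a no-glycan
    control ("none") is always included per donor.  Per donor a baseline
    composition is drawn around a shared profile (Dirichlet); treated samples
    multiply planted taxa by 2**effect (effects looked up per compound class
    in ``config.effect_map``) before renormalization, and replicates are
    Dirichlet draws around the expected composition.  ``pathogen`` names a
    taxon spiked at a fixed initial fraction (default 8 percent) in every
    sample's expected composition, emulating OD-normalized pathogen spike-ins.

    Returns ``(taxa, meta, truth)``: abundance table (rows = samples, unit
    sum), metadata (glycan_id, compound_class, donor_id, replicate), and the
    planted effect map.
    """
    rng = np.random.default_rng(config.seed + 1)
    taxa_names = [f"Genus{i + 1:02d}" for i in range(config.n_taxa)]
    effect_map = config.effect_map or default_effect_map(taxa_names)
    for cls, eff in effect_map.items():
        missing = [t for t in eff if t not in taxa_names]
        if missing:
            raise ValueError(f"effects planted on absent taxa: {missing}")
    if pathogen is not None and pathogen not in taxa_names:
        raise ValueError(f"pathogen taxon {pathogen!r} not simulated")
    if glycans is None:
        glycans = [("BRF", "SG"), ("BQM", "SG"), ("lactulose", "reference")]

    # shared profile: most taxa rare, a few dominant (lognormal abundances),
    # unless an explicit profile is configured
    if config.base_profile is not None:
        base = np.asarray(config.base_profile, dtype=float)
        if base.size != config.n_taxa or (base <= 0).any():
            raise ValueError("base_profile must be positive with n_taxa entries")
        rng.lognormal(0.0, 1.0, config.n_taxa)  # keep stream alignment
    else:
        base = rng.lognormal(0.0, 1.0, config.n_taxa)
    base = base / base.sum()
    rows, meta_rows = [], []
    for d in range(1, config.n_donors + 1):
        donor = f"D{d:02d}"
        p_donor = rng.dirichlet(config.donor_concentration * config.n_taxa * base)
        p_donor = np.maximum(p_donor, 1e-12)
        for glycan, cls in [("none", "none"), *glycans]:
            expected = p_donor.copy()
            for taxon, eff in effect_map.get(cls, {}).items():
                expected[taxa_names.index(taxon)] *= 2.0**eff
            expected = expected / expected.sum()
            if pathogen is not None:
                j = taxa_names.index(pathogen)
                expected = expected * (1.0 - pathogen_fraction) / (
                    expected.sum() - expected[j] + 1e-300)
                expected[j] = pathogen_fraction
                expected = expected / expected.sum()
            for rep in range(1, config.n_replicates + 1):
                obs = rng.dirichlet(config.replicate_concentration * expected)
                rows.append(obs / obs.sum())
                meta_rows.append({"sample_id": f"{donor}_{glycan}_r{rep}",
                                  "glycan_id": glycan, "compound_class": cls,
                                  "donor_id": donor, "replicate": rep})
    meta = pd.DataFrame(meta_rows)
    taxa = pd.DataFrame(rows, columns=taxa_names, index=meta["sample_id"])
    meta = meta.set_index("sample_id")
    return taxa, meta, effect_map


def generate_scfa_peaks(true_concentrations, calibration_truth: dict | None = None,
                        is_area: float = 50_000.0, noise_sd: float = 0.0,
                        seed: int = 0,
                        standard_levels=(2.5, 10.0, 15.0, 20.0, 30.0, 40.0)):
    """SCFA peak-area tables with linear detector response + internal standard.

    ``true_concentrations`` maps sample_id -> {analyte: mM}.  The detector
    response is analyte_area = slope * conc * is_area * (1 + noise), i.e. the
    internal-standard-normalized response is linear in concentration with
    zero intercept.  Returns ``(samples, standards)`` peak tables with
    columns (sample_id, analyte, area, is_area).
    """
    if calibration_truth is None:
        calibration_truth = {"butyrate": 0.12, "propionate": 0.09}
    rng = np.random.default_rng(seed)

    def area(analyte, conc):
        if conc < 0:
            raise ValueError(f"negative concentration for {analyte}: {conc}")
        slope = calibration_truth[analyte]
        noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
        return slope * conc * is_area * (1.0 + noise)

    sample_rows = [
        {"sample_id": sid, "analyte": analyte, "area": area(analyte, conc),
         "is_area": is_area}
        for sid, concs in true_concentrations.items()
        for analyte, conc in concs.items()
    ]
    std_rows = [
        {"sample_id": f"std_{level:g}mM", "analyte": analyte, "conc_mm": level,
         "area": area(analyte, level), "is_area": is_area}
        for analyte in calibration_truth
        for level in standard_levels
    ]
    return pd.DataFrame(sample_rows), pd.DataFrame(std_rows)


def generate_survival_weights(group_hazards: dict, n_per_group: int = 12,
                              horizon_days: float = 14.0, seed: int = 0,
                              weight_drift: dict | None = None,
                              weight_noise_sd: float = 0.5):
    """Survival records and body-weight trajectories per treatment group.

    Event times are exponential with the group's constant hazard (per day),
    censored at the horizon; body weights start at 100 percent and drift
    linearly at the group's rate (percent/day, default 0) plus noise.
    Returns ``(survival, weights)`` tidy DataFrames.
    """
    for g, h in group_hazards.items():
        if h < 0:
            raise ValueError(f"negative hazard for group {g!r}")
    weight_drift = weight_drift or {}
    rng = np.random.default_rng(seed)
    days = np.arange(0.0, horizon_days + 1e-9, 1.0)
    surv_rows, weight_rows = [], []
    for group, hazard in group_hazards.items():
        drift = weight_drift.get(group, 0.0)
        for i in range(1, n_per_group + 1):
            aid = f"{group}_{i:02d}"
            if hazard == 0:
                time, event = horizon_days, False
            else:
                raw = rng.exponential(1.0 / hazard)
                time, event = (raw, True) if raw < horizon_days else (horizon_days, False)
            surv_rows.append({"animal_id": aid, "group": group,
                              "time": float(time), "event": event})
            alive = days <= time
            w = 100.0 + drift * days[alive]
            if weight_noise_sd:
                w = w + rng.normal(0.0, weight_noise_sd, alive.sum())
            for day, wt in zip(days[alive], w):
                weight_rows.append({"animal_id": aid, "group": group,
                                    "day": float(day), "weight_pct": float(wt)})
    return pd.DataFrame(surv_rows), pd.DataFrame(weight_rows)
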