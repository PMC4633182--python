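"""Hierarchical synthetic morphometric data for the species-group.

Workers are simulated in ratio space: cephalic size CS carries the body
size, and each dimensionless trait ratio is drawn around a
species-specific mean with an optional linear size (allometry) term.
Both CS and the ratios receive a shared nest-level random effect plus a
worker-level residual, so the variance decomposes between and within
nests the way nest-sample data do.  Traits are reconstructed from the
ratios (CL and CWb are solved from CS and the CL/CWb ratio), which
keeps every simulated measurement positive.

The bundled profiles encode the published per-species statistics of the
eighteen *Temnothorax nylanderi*-group species: cephalic size and ten
trait ratios with their printed means and ranges, spine deviation
angles, antennomere counts and coarse ranges.  The remaining trait
ratios, which are not printed per species, use genus-plausible
baselines with per-species offsets chosen to be consistent with the
published identification key and discriminant functions (see the
methods note).  Standard deviations are imputed from printed ranges by
the (max − min)/4 rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import TRAIT_NAMES, Region, SpecimenRecord, TraitVector, ValidationError

__all__ = [
    "SpeciesProfile",
    "GeneratorConfig",
    "profile_from_summary",
    "profiles_from_config",
    "generate_dataset",
    "nylanderi_group_profiles",
    "scale_separation",
]

#: Ratios a profile must provide to reconstruct all 22 traits.
RECONSTRUCTION_RATIOS: tuple[str, ...] = tuple(
    ["CL/CWb", "PoOC/CL"]
    + [f"{t}/CS" for t in TRAIT_NAMES if t not in ("CL", "CWb", "PoOC")]
)


@dataclass(frozen=True)
class SpeciesProfile:
    """Distributional summary of one species in ratio space."""

    name: str
    cs_mean: float
    cs_sd: float
    ratio_means: Mapping[str, float]
    ratio_sds: Mapping[str, float]
    allometry: Mapping[str, float] = field(default_factory=dict)  # per μm of CS
    antennomere_count: int = 12
    spine_angle_range: tuple[float, float] = (35.0, 45.0)
    region: Region = Region.UNKNOWN
    n_nests: int = 10

    def __post_init__(self) -> None:
        if self.cs_sd < 0:
            raise ValidationError("cs_sd must be non-negative")
        for r, m in self.ratio_means.items():
            if m <= 0:
                raise ValidationError(f"{self.name}: ratio mean {r} must be positive")
        for r, s in self.ratio_sds.items():
            if s < 0:
                raise ValidationError(f"{self.name}: ratio sd {r} must be non-negative")
        missing = [r for r in RECONSTRUCTION_RATIOS if r not in self.ratio_means]
        if missing:
            raise ValidationError(f"{self.name}: profile lacks ratios {missing}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design for one simulated dataset.

    ``nest_effect_sd_fraction`` is the share of each trait's total
    variance attributed to the nest level (colony identity); the
    remainder is worker-level residual.
    """

    profiles: Sequence[SpeciesProfile]
    nests_per_species: int | None = None  # None: use each profile's n_nests
    workers_per_nest: int | tuple[int, int] = 3
    nest_effect_sd_fraction: float = 0.3
    lognormal_cs: bool = False
    round_to_um: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValidationError("at least one species profile required")
        if self.nests_per_species is not None and self.nests_per_species < 1:
            raise ValidationError("nests_per_species must be >= 1")
        if not 0.0 <= self.nest_effect_sd_fraction <= 1.0:
            raise ValidationError("nest_effect_sd_fraction must lie in [0, 1]")


def profile_from_summary(
    name: str,
    summary_rows: Mapping[str, Mapping[str, float]],
    **kwargs,
) -> SpeciesProfile:
    """Build a profile from per-ratio summary rows.

    Each row gives ``mean`` plus either ``sd`` or a ``min``/``max``
    range; a range is converted with the sd ≈ (max − min)/4 rule.  A
    mean-only row gets sd 0 with a warning.  A ``CS`` row is required.
    """
    if "CS" not in summary_rows:
        raise ValidationError("summary must include a CS row")

    def _sd(key: str, row: Mapping[str, float]) -> float:
        if "sd" in row:
            return float(row["sd"])
        if "min" in row and "max" in row:
            return (float(row["max"]) - float(row["min"])) / 4.0
        warnings.warn(f"{name}: no sd or range for {key}; using sd=0", stacklevel=2)
        return 0.0

    cs_row = summary_rows["CS"]
    means = {k: float(v["mean"]) for k, v in summary_rows.items() if k != "CS"}
    sds = {k: _sd(k, v) for k, v in summary_rows.items() if k != "CS"}
    return SpeciesProfile(
        name=name,
        cs_mean=float(cs_row["mean"]),
        cs_sd=_sd("CS", cs_row),
        ratio_means=means,
        ratio_sds=sds,
        **kwargs,
    )


def profiles_from_config(path) -> list[SpeciesProfile]:
    """Load species profiles from a YAML (or JSON) config file.

    Expected layout::

        species:
          - name: lichtensteini
            CS: {mean: 535, min: 474, max: 585}
            ratios:
              SPST/CS: {mean: 0.346, min: 0.324, max: 0.377}
              ...                       # one row per reconstruction ratio
            antennomere_count: 12       # optional, default 12
            spine_angle_range: [20, 25] # optional
            region: EUROPE_MAINLAND     # optional
            n_nests: 85                 # optional

    Each row gives a mean plus either an sd or a min/max range
    (converted by the (max − min)/4 rule, as in profile_from_summary).
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    profiles = []
    for entry in data["species"]:
        rows = {"CS": entry["CS"], **entry["ratios"]}
        kwargs = {}
        if "antennomere_count" in entry:
            kwargs["antennomere_count"] = int(entry["antennomere_count"])
        if "spine_angle_range" in entry:
            lo, hi = entry["spine_angle_range"]
            kwargs["spine_angle_range"] = (float(lo), float(hi))
        if "region" in entry:
            kwargs["region"] = Region.coerce(entry["region"])
        if "n_nests" in entry:
            kwargs["n_nests"] = int(entry["n_nests"])
        profiles.append(profile_from_summary(entry["name"], rows, **kwargs))
    return profiles


def _reconstruct_traits(cs: float, ratios: Mapping[str, float]) -> dict[str, float]:
    r = ratios["CL/CWb"]
    cl = 2.0 * cs * r / (1.0 + r)
    cwb = 2.0 * cs / (1.0 + r)
    out = {"CL": cl, "CWb": cwb, "PoOC": ratios["PoOC/CL"] * cl}
    for t in TRAIT_NAMES:
        if t not in out:
            out[t] = ratios[f"{t}/CS"] * cs
    return out


_MAX_RESAMPLE = 100


def generate_dataset(config: GeneratorConfig) -> list[SpecimenRecord]:
    """Simulate a full worker dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    f_nest = config.nest_effect_sd_fraction
    records: list[SpecimenRecord] = []
    for profile in config.profiles:
        n_nests = config.nests_per_species or profile.n_nests
        cs_sd_nest = profile.cs_sd * np.sqrt(f_nest)
        cs_sd_resid = profile.cs_sd * np.sqrt(1.0 - f_nest)
        for j in range(n_nests):
            nest_id = f"SYN:{profile.name}-{j + 1}N-20200101-{j + 1}"
            if isinstance(config.workers_per_nest, tuple):
                lo, hi = config.workers_per_nest
                n_workers = int(rng.integers(lo, hi + 1))
            else:
                n_workers = int(config.workers_per_nest)
            u_cs = rng.normal(0.0, cs_sd_nest)
            v = {
                r: rng.normal(0.0, profile.ratio_sds.get(r, 0.0) * np.sqrt(f_nest))
                for r in RECONSTRUCTION_RATIOS
            }
            for i in range(n_workers):
                for attempt in range(_MAX_RESAMPLE):
                    if config.lognormal_cs:
                        mu = np.log(profile.cs_mean)
                        sigma = profile.cs_sd / profile.cs_mean
                        cs = float(
                            np.exp(mu + u_cs / profile.cs_mean + rng.normal(0, sigma)
                                   * np.sqrt(1.0 - f_nest))
                        )
                    else:
                        cs = profile.cs_mean + u_cs + rng.normal(0.0, cs_sd_resid)
                    dcs = cs - profile.cs_mean
                    ratios = {}
                    for r in RECONSTRUCTION_RATIOS:
                        sd_resid = profile.ratio_sds.get(r, 0.0) * np.sqrt(1.0 - f_nest)
                        ratios[r] = (
                            profile.ratio_means[r]
                            + profile.allometry.get(r, 0.0) * dcs
                            + v[r]
                            + rng.normal(0.0, sd_resid)
                        )
                    if cs <= 0 or any(x <= 0 for x in ratios.values()):
                        continue
                    values = _reconstruct_traits(cs, ratios)
                    if config.round_to_um:
                        values = {k: round(val) for k, val in values.items()}
                    try:
                        traits = TraitVector(values, check_window=False)
                    except ValidationError:
                        continue
                    break
                else:
                    raise ValidationError(
                        f"could not draw a valid worker for {profile.name} "
                        f"after {_MAX_RESAMPLE} attempts"
                    )
                lo_a, hi_a = profile.spine_angle_range
                records.append(
                    SpecimenRecord(
                        specimen_id=f"{nest_id}-w{i + 1}",
                        nest_id=nest_id,
                        traits=traits,
                        species=profile.name,
                        antennomere_count=profile.antennomere_count,
                        spine_angle_deg=float(rng.uniform(lo_a, hi_a)),
                        region=profile.region,
                    )
                )
    return records


def _trait_moments(p: SpeciesProfile) -> tuple[np.ndarray, np.ndarray]:
    """Per-trait mean and variance implied by a profile (delta method).

    A trait is ratio·CS (CL and CWb go through CL/CWb, PoOC through
    PoOC/CL), so its variance combines the ratio's spread at mean size
    with the size spread at the mean ratio.
    """
    means = _reconstruct_traits(p.cs_mean, p.ratio_means)
    r = p.ratio_means["CL/CWb"]
    sd_r = p.ratio_sds.get("CL/CWb", 0.0)
    var = {}
    # CL = CS·2r/(1+r), CWb = CS·2/(1+r)
    g, dg = 2 * r / (1 + r), 2 / (1 + r) ** 2
    h, dh = 2 / (1 + r), -2 / (1 + r) ** 2
    var["CL"] = (p.cs_mean * dg * sd_r) ** 2 + (g * p.cs_sd) ** 2
    var["CWb"] = (p.cs_mean * dh * sd_r) ** 2 + (h * p.cs_sd) ** 2
    q, sd_q = p.ratio_means["PoOC/CL"], p.ratio_sds.get("PoOC/CL", 0.0)
    var["PoOC"] = (means["CL"] * sd_q) ** 2 + q**2 * var["CL"]
    for t in TRAIT_NAMES:
        if t in var:
            continue
        ratio = f"{t}/CS"
        m, s = p.ratio_means[ratio], p.ratio_sds.get(ratio, 0.0)
        var[t] = (p.cs_mean * s) ** 2 + (m * p.cs_sd) ** 2
    mean_vec = np.array([means[t] for t in TRAIT_NAMES])
    var_vec = np.array([var[t] for t in TRAIT_NAMES])
    return mean_vec, var_vec


def scale_separation(
    profiles: Sequence[SpeciesProfile],
    min_separation: float,
) -> list[SpeciesProfile]:
    """Shrink all sds uniformly until every pair of profiles is at least
    ``min_separation`` pooled standard deviations apart.

    Separation is measured where the downstream clustering operates: on
    the 22 reconstructed trait means, each coordinate scaled by the
    pooled within-species trait sd implied by the profiles (delta
    method, combining ratio spread and body-size spread).  Because
    agglomeration works on distances in p-dimensional space, where the
    typical distance between two same-species points is √(2p) per-trait
    sds, the pairwise mean distance is expressed in units of that
    multivariate noise scale.  Profiles already separated are returned
    unchanged; otherwise every ratio sd and the CS sd are multiplied by
    one common factor, leaving all means untouched.
    """
    moments = [_trait_moments(p) for p in profiles]
    means = np.array([m for m, _ in moments])
    pooled = np.sqrt(np.mean([v for _, v in moments], axis=0))
    pooled[pooled == 0] = np.inf
    z = means / pooled
    d = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    p_dim = means.shape[1]
    current = float(d.min()) / np.sqrt(2 * p_dim)
    if current >= min_separation:
        return list(profiles)
    factor = current / min_separation
    return [
        replace(
            p,
            cs_sd=p.cs_sd * factor,
            ratio_sds={r: s * factor for r, s in p.ratio_sds.items()},
        )
        for p in profiles
    ]


# ---------------------------------------------------------------------------
# Bundled profiles for the eighteen species of the group.
#
# For each species: CS (mean, min, max) in μm and the ten ratios whose
# per-species mean and range are printed in the worker accounts.  The
# antennomere count, propodeal-spine deviation angle range and coarse
# geographic range come from the same accounts and the key.
# ---------------------------------------------------------------------------

_EM = Region.EUROPE_MAINLAND
_AC = Region.ANATOLIA_OR_CRETE
_CW = Region.CENTRAL_WEST_EUROPE
_EE = Region.EAST_EUROPE_BALKANS_CAUCASUS

# species: (CS(mean,min,max), {ratio: (mean,min,max)}, angle, antennomeres,
#           region, n_nests)
_PRINTED: dict[str, tuple] = {
    "angulinodis": (
        (626, 594, 657),
        {
            "CL/CWb": (1.203, 1.171, 1.222), "PoOC/CL": (0.368, 0.356, 0.378),
            "EL/CS": (0.265, 0.257, 0.274), "FRS/CS": (0.374, 0.366, 0.388),
            "SL/CS": (0.808, 0.797, 0.816), "MW/CS": (0.621, 0.610, 0.636),
            "SPST/CS": (0.355, 0.332, 0.369), "SPBA/CS": (0.285, 0.262, 0.304),
            "SPWI/CS": (0.409, 0.390, 0.419), "SPTI/CS": (0.386, 0.366, 0.398),
        },
        (32, 38), 12, _EM, 8,
    ),
    "angustifrons": (
        (546, 500, 590),
        {
            "CL/CWb": (1.224, 1.193, 1.254), "PoOC/CL": (0.389, 0.377, 0.401),
            "EL/CS": (0.254, 0.247, 0.263), "FRS/CS": (0.328, 0.320, 0.349),
            "SL/CS": (0.821, 0.807, 0.832), "MW/CS": (0.601, 0.588, 0.620),
            "SPST/CS": (0.231, 0.200, 0.264), "SPBA/CS": (0.259, 0.242, 0.275),
            "SPWI/CS": (0.298, 0.282, 0.319), "SPTI/CS": (0.284, 0.265, 0.298),
        },
        (50, 55), 12, _AC, 16,
    ),
    "lucidus": (
        (618, 560, 670),
        {
            "CL/CWb": (1.173, 1.139, 1.221), "PoOC/CL": (0.380, 0.368, 0.400),
            "EL/CS": (0.262, 0.247, 0.276), "FRS/CS": (0.370, 0.356, 0.389),
            "SL/CS": (0.796, 0.767, 0.832), "MW/CS": (0.621, 0.599, 0.636),
            "SPST/CS": (0.236, 0.190, 0.259), "SPBA/CS": (0.258, 0.241, 0.280),
            "SPWI/CS": (0.304, 0.272, 0.339), "SPTI/CS": (0.290, 0.261, 0.318),
        },
        (45, 50), 12, _AC, 24,
    ),
    "similis": (
        (571, 505, 635),
        {
            "CL/CWb": (1.183, 1.145, 1.233), "PoOC/CL": (0.386, 0.371, 0.398),
            "EL/CS": (0.263, 0.245, 0.270), "FRS/CS": (0.361, 0.352, 0.369),
            "SL/CS": (0.802, 0.775, 0.830), "MW/CS": (0.624, 0.606, 0.641),
            "SPST/CS": (0.245, 0.220, 0.267), "SPBA/CS": (0.277, 0.261, 0.290),
            "SPWI/CS": (0.321, 0.299, 0.347), "SPTI/CS": (0.321, 0.291, 0.326),
        },
        (47, 52), 12, _AC, 13,
    ),
    "subtilis": (
        (556, 499, 628),
        {
            "CL/CWb": (1.189, 1.135, 1.238), "PoOC/CL": (0.388, 0.374, 0.408),
            "EL/CS": (0.249, 0.228, 0.268), "FRS/CS": (0.360, 0.335, 0.375),
            "SL/CS": (0.782, 0.735, 0.810), "MW/CS": (0.623, 0.592, 0.648),
            "SPST/CS": (0.192, 0.159, 0.230), "SPBA/CS": (0.272, 0.247, 0.300),
            "SPWI/CS": (0.282, 0.266, 0.336), "SPTI/CS": (0.282, 0.256, 0.322),
        },
        (47, 52), 12, _AC, 55,
    ),
    "flavicornis": (
        (496, 465, 516),
        {
            "CL/CWb": (1.266, 1.226, 1.299), "PoOC/CL": (0.384, 0.370, 0.394),
            "EL/CS": (0.262, 0.244, 0.271), "FRS/CS": (0.364, 0.351, 0.373),
            "SL/CS": (0.803, 0.784, 0.817), "MW/CS": (0.637, 0.622, 0.653),
            "SPST/CS": (0.358, 0.303, 0.420), "SPBA/CS": (0.338, 0.322, 0.358),
            "SPWI/CS": (0.458, 0.402, 0.506), "SPTI/CS": (0.432, 0.373, 0.482),
        },
        (40, 45), 11, _EM, 12,
    ),
    "laconicus": (
        (546, 500, 590),
        {
            "CL/CWb": (1.228, 1.199, 1.258), "PoOC/CL": (0.396, 0.383, 0.403),
            "EL/CS": (0.244, 0.229, 0.265), "FRS/CS": (0.342, 0.329, 0.360),
            "SL/CS": (0.785, 0.766, 0.804), "MW/CS": (0.610, 0.587, 0.629),
            "SPST/CS": (0.411, 0.391, 0.429), "SPBA/CS": (0.283, 0.257, 0.311),
            "SPWI/CS": (0.438, 0.401, 0.485), "SPTI/CS": (0.413, 0.381, 0.462),
        },
        (20, 25), 12, _EM, 16,
    ),
    "lichtensteini": (
        (535, 474, 585),
        {
            "CL/CWb": (1.225, 1.181, 1.261), "PoOC/CL": (0.401, 0.386, 0.418),
            "EL/CS": (0.248, 0.232, 0.270), "FRS/CS": (0.356, 0.336, 0.380),
            "SL/CS": (0.787, 0.763, 0.809), "MW/CS": (0.608, 0.570, 0.631),
            "SPST/CS": (0.346, 0.324, 0.377), "SPBA/CS": (0.272, 0.250, 0.302),
            "SPWI/CS": (0.391, 0.335, 0.428), "SPTI/CS": (0.371, 0.318, 0.411),
        },
        (20, 25), 12, _EM, 85,
    ),
    "crasecundus": (
        (614, 539, 719),
        {
            # printed PoOC/CL mean (0.374) contradicts its own printed
            # range; the range midpoint is used
            "CL/CWb": (1.155, 1.121, 1.196), "PoOC/CL": (0.3915, 0.378, 0.405),
            "EL/CS": (0.255, 0.236, 0.280), "FRS/CS": (0.374, 0.359, 0.397),
            "SL/CS": (0.791, 0.763, 0.836), "MW/CS": (0.631, 0.612, 0.662),
            "SPST/CS": (0.289, 0.253, 0.322), "SPBA/CS": (0.298, 0.279, 0.321),
            "SPWI/CS": (0.350, 0.311, 0.392), "SPTI/CS": (0.331, 0.300, 0.369),
        },
        (32, 35), 12, _EE, 57,
    ),
    "crassispinus": (
        (623, 544, 688),
        {
            "CL/CWb": (1.140, 1.100, 1.180), "PoOC/CL": (0.390, 0.379, 0.403),
            "EL/CS": (0.256, 0.247, 0.268), "FRS/CS": (0.377, 0.362, 0.399),
            "SL/CS": (0.784, 0.756, 0.811), "MW/CS": (0.626, 0.509, 0.662),
            "SPST/CS": (0.329, 0.288, 0.356), "SPBA/CS": (0.312, 0.282, 0.339),
            "SPWI/CS": (0.389, 0.362, 0.421), "SPTI/CS": (0.366, 0.342, 0.397),
        },
        (32, 42), 12, _EE, 42,
    ),
    "nylanderi": (
        (625, 587, 678),
        {
            "CL/CWb": (1.140, 1.121, 1.160), "PoOC/CL": (0.391, 0.379, 0.402),
            "EL/CS": (0.254, 0.245, 0.268), "FRS/CS": (0.373, 0.354, 0.383),
            "SL/CS": (0.777, 0.757, 0.798), "MW/CS": (0.624, 0.610, 0.646),
            "SPST/CS": (0.280, 0.265, 0.297), "SPBA/CS": (0.280, 0.263, 0.294),
            "SPWI/CS": (0.343, 0.321, 0.362), "SPTI/CS": (0.320, 0.298, 0.339),
        },
        (35, 42), 12, _CW, 20,
    ),
    "ariadnae": (
        (543, 533, 557),
        {
            "CL/CWb": (1.223, 1.196, 1.293), "PoOC/CL": (0.386, 0.373, 0.393),
            "EL/CS": (0.263, 0.260, 0.266), "FRS/CS": (0.356, 0.346, 0.369),
            "SL/CS": (0.775, 0.758, 0.795), "MW/CS": (0.611, 0.602, 0.618),
            "SPST/CS": (0.237, 0.220, 0.249), "SPBA/CS": (0.278, 0.248, 0.287),
            "SPWI/CS": (0.314, 0.303, 0.336), "SPTI/CS": (0.300, 0.289, 0.322),
        },
        (45, 50), 12, _AC, 5,
    ),
    "helenae": (
        (566, 510, 627),
        {
            "CL/CWb": (1.197, 1.152, 1.242), "PoOC/CL": (0.400, 0.384, 0.424),
            "EL/CS": (0.251, 0.238, 0.270), "FRS/CS": (0.357, 0.335, 0.373),
            "SL/CS": (0.783, 0.758, 0.808), "MW/CS": (0.611, 0.580, 0.634),
            "SPST/CS": (0.255, 0.205, 0.299), "SPBA/CS": (0.281, 0.255, 0.319),
            "SPWI/CS": (0.334, 0.290, 0.387), "SPTI/CS": (0.320, 0.277, 0.370),
        },
        (45, 50), 12, _EM, 53,
    ),
    "parvulus": (
        (550, 488, 586),
        {
            "CL/CWb": (1.184, 1.147, 1.214), "PoOC/CL": (0.405, 0.392, 0.413),
            "EL/CS": (0.250, 0.237, 0.262), "FRS/CS": (0.361, 0.353, 0.376),
            "SL/CS": (0.778, 0.763, 0.796), "MW/CS": (0.618, 0.599, 0.636),
            "SPST/CS": (0.306, 0.278, 0.331), "SPBA/CS": (0.292, 0.273, 0.312),
            "SPWI/CS": (0.384, 0.353, 0.415), "SPTI/CS": (0.364, 0.332, 0.395),
        },
        (38, 42), 12, _EM, 29,
    ),
    "artvinensis": (
        (582, 540, 634),
        {
            "CL/CWb": (1.240, 1.206, 1.263), "PoOC/CL": (0.384, 0.375, 0.389),
            "EL/CS": (0.247, 0.239, 0.260), "FRS/CS": (0.367, 0.357, 0.375),
            "SL/CS": (0.794, 0.776, 0.813), "MW/CS": (0.612, 0.598, 0.626),
            "SPST/CS": (0.265, 0.227, 0.288), "SPBA/CS": (0.278, 0.265, 0.301),
            "SPWI/CS": (0.331, 0.296, 0.350), "SPTI/CS": (0.313, 0.280, 0.337),
        },
        (42, 48), 12, _AC, 15,
    ),
    "schoedli": (
        (652, 572, 696),
        {
            "CL/CWb": (1.172, 1.143, 1.196), "PoOC/CL": (0.368, 0.360, 0.385),
            "EL/CS": (0.268, 0.255, 0.282), "FRS/CS": (0.372, 0.363, 0.379),
            "SL/CS": (0.784, 0.764, 0.805), "MW/CS": (0.632, 0.613, 0.650),
            "SPST/CS": (0.261, 0.232, 0.282), "SPBA/CS": (0.288, 0.282, 0.298),
            "SPWI/CS": (0.327, 0.305, 0.342), "SPTI/CS": (0.310, 0.293, 0.328),
        },
        (40, 45), 12, _AC, 11,
    ),
    "sordidulus": (
        (574, 518, 607),
        {
            "CL/CWb": (1.238, 1.192, 1.278), "PoOC/CL": (0.374, 0.363, 0.390),
            "EL/CS": (0.266, 0.258, 0.280), "FRS/CS": (0.366, 0.353, 0.378),
            "SL/CS": (0.785, 0.763, 0.809), "MW/CS": (0.615, 0.599, 0.640),
            "SPST/CS": (0.258, 0.227, 0.281), "SPBA/CS": (0.273, 0.257, 0.291),
            "SPWI/CS": (0.306, 0.280, 0.331), "SPTI/CS": (0.288, 0.266, 0.312),
        },
        (42, 48), 12, _EM, 15,
    ),
    "tergestinus": (
        (592, 523, 665),
        {
            "CL/CWb": (1.206, 1.169, 1.253), "PoOC/CL": (0.384, 0.373, 0.400),
            "EL/CS": (0.258, 0.237, 0.280), "FRS/CS": (0.361, 0.347, 0.380),
            "SL/CS": (0.799, 0.781, 0.824), "MW/CS": (0.620, 0.588, 0.652),
            "SPST/CS": (0.276, 0.220, 0.335), "SPBA/CS": (0.273, 0.248, 0.295),
            "SPWI/CS": (0.333, 0.283, 0.372), "SPTI/CS": (0.312, 0.270, 0.346),
        },
        (45, 50), 12, _EM, 49,
    ),
}

# Genus-plausible baselines for the trait/CS ratios not printed per
# species, with per-species offsets consistent with the key couplets
# and the printed discriminant-function group means.
_BASELINE = {
    "ML/CS": 1.21, "NOdL/CS": 0.27, "NOH/CS": 0.165, "NOL/CS": 0.255,
    "PEH/CS": 0.385, "PEW/CS": 0.26, "PL/CS": 0.41, "PPH/CS": 0.30,
    "PPL/CS": 0.23, "PPW/CS": 0.35, "SPL/CS": 0.16,
}

_OVERRIDES: dict[str, dict[str, float]] = {
    "parvulus": {"NOH/CS": 0.150},
    "angustifrons": {"NOH/CS": 0.148},
    "similis": {"NOH/CS": 0.145, "PEH/CS": 0.348, "ML/CS": 1.245},
    "helenae": {"NOH/CS": 0.152, "ML/CS": 1.200},
    "angulinodis": {"NOH/CS": 0.172, "PEH/CS": 0.405},
    "crassispinus": {"NOH/CS": 0.170, "PEH/CS": 0.372},
    "nylanderi": {"NOH/CS": 0.170},
    "crasecundus": {"NOH/CS": 0.170},
    "lucidus": {"NOH/CS": 0.168, "NOL/CS": 0.265, "NOdL/CS": 0.29},
    "ariadnae": {"NOH/CS": 0.172, "NOL/CS": 0.238, "NOdL/CS": 0.245},
    "artvinensis": {"NOH/CS": 0.160, "NOL/CS": 0.262, "PEW/CS": 0.30},
    "schoedli": {},
    "sordidulus": {"NOH/CS": 0.170, "PL/CS": 0.425, "NOL/CS": 0.285, "ML/CS": 1.23},
    "tergestinus": {"NOH/CS": 0.170, "PL/CS": 0.405, "NOL/CS": 0.245},
}

#: Relative sd assumed for ratios without a printed range.
_BASELINE_REL_SD = 0.025


def nylanderi_group_profiles() -> list[SpeciesProfile]:
    """The eighteen bundled species profiles of the species-group."""
    profiles = []
    for name, (cs, printed, angle, ant, region, n_nests) in _PRINTED.items():
        rows: dict[str, dict[str, float]] = {
            "CS": {"mean": cs[0], "min": cs[1], "max": cs[2]}
        }
        for r, (m, lo, hi) in printed.items():
            rows[r] = {"mean": m, "min": lo, "max": hi}
        overrides = _OVERRIDES.get(name, {})
        for r, base in _BASELINE.items():
            m = overrides.get(r, base)
            rows[r] = {"mean": m, "sd": m * _BASELINE_REL_SD}
        profiles.append(
            profile_from_summary(
                name,
                rows,
                antennomere_count=ant,
                spine_angle_range=(float(angle[0]), float(angle[1])),
                region=region,
                n_nests=n_nests,
            )
        )
    return profiles
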