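"""Core data model for worker morphometrics.

The measurement protocol records 22 linear distances (in micrometres) on
each worker ant: head capsule (CL, CWb, PoOC, FRS, EL, SL), mesosoma
(ML, MW), propodeal spines (SPL, SPBA, SPST, SPTI, SPWI), petiole
(NOdL, NOH, NOL, PEH, PEW, PL) and postpetiole (PPH, PPL, PPW).
Body size is summarised by cephalic size CS = (CL + CWb) / 2, and most
taxonomic decisions operate on dimensionless trait ratios, chiefly the
trait/CS family, evaluated on nest-sample means.
"""

from __future__ import annotations

import re
import statistics
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TRAIT_NAMES",
    "RATIO_NAMES",
    "Region",
    "ValidationError",
    "TraitVector",
    "RatioVector",
    "SpecimenRecord",
    "NestSample",
    "compute_cs",
    "compute_ratios",
    "aggregate_nests",
]

#: Canonical order of the 22 recorded traits (all lengths in μm).
TRAIT_NAMES: tuple[str, ...] = (
    "CL", "CWb", "EL", "FRS", "ML", "MW", "NOdL", "NOH", "NOL", "PEH",
    "PEW", "PL", "PoOC", "PPH", "PPL", "PPW", "SL", "SPL", "SPBA",
    "SPST", "SPTI", "SPWI",
)

# Spelling variants that occur in print (PoOc/PoOC/POC, NOdL/NodL).
_TRAIT_ALIASES: dict[str, str] = {name.upper(): name for name in TRAIT_NAMES}
_TRAIT_ALIASES["POC"] = "PoOC"

#: Default plausibility window for a single linear measurement (μm).
PLAUSIBLE_UM = (100.0, 2000.0)


def canonical_trait(name: str) -> str:
    """Resolve a trait-column spelling variant to its canonical name."""
    try:
        return _TRAIT_ALIASES[name.strip().upper()]
    except KeyError:
        raise KeyError(f"unknown trait name: {name!r}") from None


class ValidationError(ValueError):
    """A morphometric record violates a structural invariant."""


class Region(Enum):
    """Coarse geographic classes used by the identification key."""

    EUROPE_MAINLAND = "EUROPE_MAINLAND"
    ANATOLIA_OR_CRETE = "ANATOLIA_OR_CRETE"
    CENTRAL_WEST_EUROPE = "CENTRAL_WEST_EUROPE"
    EAST_EUROPE_BALKANS_CAUCASUS = "EAST_EUROPE_BALKANS_CAUCASUS"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def coerce(cls, value: "Region | str | None") -> "Region":
        if value is None:
            return cls.UNKNOWN
        if isinstance(value, cls):
            return value
        return cls[str(value).strip().upper()]

    @property
    def is_mainland_europe(self) -> bool:
        return self in (
            Region.EUROPE_MAINLAND,
            Region.CENTRAL_WEST_EUROPE,
            Region.EAST_EUROPE_BALKANS_CAUCASUS,
        )


@dataclass(frozen=True)
class TraitVector(Mapping):
    """The 22 linear measurements (μm) of one worker.

    Structural invariants (always enforced): every value positive,
    PoOC < CL, NOH ≤ PEH and SPBA < SPWI.  The plausibility window
    check (each value inside ``window``) can be disabled for data known
    to contain legitimately small parts (e.g. petiolar node heights of
    very small workers).
    """

    values: Mapping[str, float]
    check_window: bool = True
    window: tuple[float, float] = PLAUSIBLE_UM

    def __post_init__(self) -> None:
        vals: dict[str, float] = {}
        for name in TRAIT_NAMES:
            if name not in self.values:
                raise ValidationError(f"missing trait: {name}")
            v = float(self.values[name])
            if not v > 0:
                raise ValidationError(f"trait {name} must be positive, got {v}")
            vals[name] = v
        extra = set(self.values) - set(TRAIT_NAMES)
        if extra:
            raise ValidationError(f"unknown trait(s): {sorted(extra)}")
        if not vals["PoOC"] < vals["CL"]:
            raise ValidationError("PoOC must be smaller than CL")
        if vals["NOH"] > vals["PEH"]:
            raise ValidationError("NOH (node height) cannot exceed PEH (petiole height)")
        if not vals["SPBA"] < vals["SPWI"]:
            raise ValidationError("SPBA (minimum spine base distance) must be below SPWI")
        if self.check_window:
            lo, hi = self.window
            for name, v in vals.items():
                if not lo <= v <= hi:
                    raise ValidationError(
                        f"trait {name}={v} μm outside plausibility window [{lo}, {hi}]"
                    )
        object.__setattr__(self, "values", vals)

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self.values[canonical_trait(key)]

    def __iter__(self):
        return iter(TRAIT_NAMES)

    def __len__(self) -> int:
        return len(TRAIT_NAMES)

    def __getattr__(self, name: str) -> float:
        if name in TRAIT_NAMES:
            return self.values[name]
        raise AttributeError(name)

    @property
    def cs(self) -> float:
        return compute_cs(self)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def compute_cs(traits: Mapping[str, float]) -> float:
    """Cephalic size: the arithmetic mean of CL and CWb (μm)."""
    for name in ("CL", "CWb"):
        if name not in traits:
            raise ValidationError(f"missing trait: {name}")
        if not float(traits[name]) > 0:
            raise ValidationError(f"trait {name} must be positive")
    return (float(traits["CL"]) + float(traits["CWb"])) / 2.0


def _ratio_def(name: str) -> tuple[str, str]:
    m = re.fullmatch(r"([A-Za-z]+)/([A-Za-z]+)", name)
    if m is None:
        raise KeyError(name)
    num, den = m.group(1), m.group(2)
    num = "CS" if num.upper() == "CS" else canonical_trait(num)
    den = "CS" if den.upper() == "CS" else canonical_trait(den)
    return num, den


#: The ratio families used by the key and the differential diagnoses.
RATIO_NAMES: tuple[str, ...] = tuple(
    [f"{t}/CS" for t in TRAIT_NAMES if t not in ("CL", "CWb", "PoOC")]
    + ["CL/CWb", "PoOC/CL", "SPST/CL", "SPBA/CWb", "PoOC/NOH", "FRS/SL"]
)


@dataclass(frozen=True)
class RatioVector(Mapping):
    """Cephalic size plus a set of named dimensionless trait ratios."""

    cs: float
    ratios: Mapping[str, float]

    def __getitem__(self, key: str) -> float:
        if key.upper() == "CS":
            return self.cs
        num, den = _ratio_def(key)
        return self.ratios[f"{num}/{den}"]

    def __contains__(self, key) -> bool:
        try:
            self[key]
            return True
        except KeyError:
            return False

    def __iter__(self):
        return iter(self.ratios)

    def __len__(self) -> int:
        return len(self.ratios)


def compute_ratios(
    traits: Mapping[str, float],
    ratio_names: Sequence[str] | None = None,
) -> RatioVector:
    """Compute named trait ratios; CS is always included.

    ``ratio_names`` entries look like ``"SPST/CS"`` or ``"CL/CWb"``;
    any pair of canonical trait names (or CS) is accepted.  Unknown
    names raise KeyError listing the standard ratio vocabulary.
    """
    cs = compute_cs(traits)
    names = RATIO_NAMES if ratio_names is None else tuple(ratio_names)
    out: dict[str, float] = {}
    for name in names:
        try:
            num, den = _ratio_def(name)
        except KeyError:
            raise KeyError(
                f"unknown ratio name {name!r}; known ratios: {', '.join(RATIO_NAMES)}"
            ) from None
        nv = cs if num == "CS" else float(traits[num])
        dv = cs if den == "CS" else float(traits[den])
        if dv == 0:
            raise ZeroDivisionError(f"zero denominator in ratio {name}")
        out[f"{num}/{den}"] = nv / dv
    return RatioVector(cs=cs, ratios=out)


_NEST_ID_RE = re.compile(r"^[A-Z]{3}:.+")


@dataclass
class SpecimenRecord:
    """One measured worker with its collection metadata.

    ``nest_id`` follows the sample-code convention
    ``COUNTRY:locality-offset-date-sampleid`` (e.g.
    ``GRE:Levidi-10S-20000427-123``); the three-letter country code is
    derived from it when not given explicitly.
    """

    specimen_id: str
    nest_id: str
    traits: TraitVector
    species: str | None = None
    country: str | None = None
    antennomere_count: int | None = None
    spine_angle_deg: float | None = None
    region: Region = Region.UNKNOWN
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.region = Region.coerce(self.region)
        if self.country is None and _NEST_ID_RE.match(self.nest_id):
            self.country = self.nest_id.split(":", 1)[0]
        if self.antennomere_count is not None:
            self.antennomere_count = int(self.antennomere_count)
            if self.antennomere_count not in (11, 12):
                raise ValidationError(
                    f"antennomere_count must be 11 or 12, got {self.antennomere_count}"
                )

    def ratios(self, ratio_names: Sequence[str] | None = None) -> RatioVector:
        return compute_ratios(self.traits, ratio_names)


@dataclass
class NestSample:
    """All workers of one nest, summarised by per-trait arithmetic means.

    The nest sample is the unit of the clustering step and of the
    identification key ("the key is based on nest sample means").
    """

    nest_id: str
    specimen_ids: list[str]
    trait_means: dict[str, float]
    n_workers: int
    species: str | None = None
    ambiguous_label: bool = False
    antennomere_count: int | None = None
    spine_angle_deg: float | None = None
    region: Region = Region.UNKNOWN

    def ratios(self, ratio_names: Sequence[str] | None = None) -> RatioVector:
        return compute_ratios(self.trait_means, ratio_names)


def aggregate_nests(records: Iterable[SpecimenRecord]) -> list[NestSample]:
    """Group specimens by nest and average each trait arithmetically.

    Nests whose members carry conflicting species labels are kept but
    flagged ``ambiguous_label`` (and left unlabeled) so that supervised
    steps can exclude them.  Output is sorted by nest id and therefore
    invariant to the input row order.
    """
    by_nest: dict[str, list[SpecimenRecord]] = {}
    for rec in records:
        if not rec.nest_id:
            raise ValidationError(f"specimen {rec.specimen_id!r} has no nest_id")
        by_nest.setdefault(rec.nest_id, []).append(rec)

    nests: list[NestSample] = []
    for nest_id in sorted(by_nest):
        members = by_nest[nest_id]
        means = {
            t: statistics.fmean(m.traits[t] for m in members) for t in TRAIT_NAMES
        }
        labels = {m.species for m in members if m.species is not None}
        ambiguous = len(labels) > 1
        if ambiguous:
            warnings.warn(
                f"nest {nest_id} has conflicting species labels {sorted(labels)}; "
                "flagged ambiguous",
                stacklevel=2,
            )
        counts = {m.antennomere_count for m in members if m.antennomere_count}
        angles = [m.spine_angle_deg for m in members if m.spine_angle_deg is not None]
        regions = {m.region for m in members} - {Region.UNKNOWN}
        nests.append(
            NestSample(
                nest_id=nest_id,
                specimen_ids=[m.specimen_id for m in members],
                trait_means=means,
                n_workers=len(members),
                species=None if ambiguous else (labels.pop() if labels else None),
                ambiguous_label=ambiguous,
                antennomere_count=counts.pop() if len(counts) == 1 else None,
                spine_angle_deg=statistics.fmean(angles) if angles else None,
                region=regions.pop() if len(regions) == 1 else Region.UNKNOWN,
            )
        )
    return nests
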