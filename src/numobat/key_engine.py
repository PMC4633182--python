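"""Identification engine for the worker caste.

Two published determination tools are implemented: the 19-couplet
dichotomous key (continuous ratio thresholds, antennomere count,
propodeal-spine deviation angle and, at two couplets, geographic
region), and the registry of printed discriminant functions whose
score sign separates two taxa (or one taxon from a pooled remainder).

Both operate on nest-sample means by default; the key's author caveat
is that it also works on single specimens with high (>95%) probability.
Thresholds are strict as printed: a value exactly at a threshold, or
inside a printed between-lobe gap, is flagged a tie rather than being
assigned silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .core import RatioVector, Region
from .lda import DiscriminantFunction

__all__ = [
    "Key",
    "KeyResult",
    "MissingKeyFeature",
    "PrintedFunctionRegistry",
    "FunctionClassification",
    "load_default_key",
    "load_registry",
    "evaluate_printed",
    "classify_by_function",
    "classify_key",
]

SINGLE_SPECIMEN_CAVEAT = (
    "identification of a single worker: the key is calibrated on nest sample "
    "means and is expected to hold for single specimens with >95% probability"
)


class MissingKeyFeature(KeyError):
    """A couplet needs a feature the input does not provide."""

    def __init__(self, couplet: str, feature: str):
        super().__init__(
            f"couplet {couplet} requires feature {feature!r}, which is missing"
        )
        self.couplet = couplet
        self.feature = feature


@dataclass
class KeyResult:
    """Outcome of one key traversal."""

    taxon: str | None
    path: list[int]
    decisions: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    caveats: list[str] = field(default_factory=list)
    tie_at: int | None = None

    @property
    def is_tie(self) -> bool:
        return self.tie_at is not None


class Key:
    """A machine-readable dichotomous key (bundled or induced)."""

    def __init__(self, data: Mapping):
        self.data = dict(data)
        self.nodes: dict[str, dict] = dict(data["nodes"])
        self.root: str = data.get("root", "1")
        self.taxa: list[str] = list(data.get("taxa", []))

    @classmethod
    def from_file(cls, path: str | Path) -> "Key":
        return cls(json.loads(Path(path).read_text()))

    def classify(
        self,
        ratios: RatioVector | Mapping[str, float],
        *,
        antennomere_count: int | None = None,
        spine_angle_deg: float | None = None,
        region: Region | str | None = None,
        single_specimen: bool = False,
    ) -> KeyResult:
        """Traverse the key; returns the leaf taxon and the couplet path.

        Missing features along the traversed path raise
        :class:`MissingKeyFeature`; values at a printed threshold or
        inside a printed gap yield a tie result with no taxon.
        """
        region = Region.coerce(region)
        result = KeyResult(taxon=None, path=[])
        if single_specimen:
            result.caveats.append(SINGLE_SPECIMEN_CAVEAT)
        node_id = self.root
        while True:
            node = self.nodes[node_id]
            couplet = int(node_id) if node_id.isdigit() else node_id
            result.path.append(couplet)
            feature = node["feature"]
            ntype = node["type"]

            if ntype == "categorical":
                if feature == "antennomere_count":
                    value = antennomere_count
                else:
                    value = None
                if value is None:
                    raise MissingKeyFeature(str(node_id), feature)
                branch = "if_match" if value == node["value"] else "else"
                result.decisions.append(
                    {"couplet": couplet, "feature": feature, "value": value,
                     "went": branch}
                )
            elif ntype == "region":
                if region is Region.UNKNOWN:
                    raise MissingKeyFeature(str(node_id), feature)
                branch = "if_match" if region.value in node["match"] else "else"
                result.decisions.append(
                    {"couplet": couplet, "feature": feature,
                     "value": region.value, "went": branch}
                )
            elif ntype == "threshold":
                if feature == "spine_angle_deg":
                    value = spine_angle_deg
                else:
                    try:
                        value = ratios[feature]
                    except KeyError:
                        value = None
                if value is None:
                    raise MissingKeyFeature(str(node_id), feature)
                t = node["threshold"]
                hi_min = node.get("gap_high", t)
                lo_max = node.get("gap_low", t)
                if value > hi_min:
                    branch = "high"
                elif value < lo_max:
                    branch = "low"
                else:  # at a threshold or inside the printed gap
                    result.tie_at = couplet
                    result.notes.append(
                        f"couplet {couplet}: {feature}={value} lies at the "
                        "printed threshold/gap; no assignment made"
                    )
                    return result
                result.decisions.append(
                    {"couplet": couplet, "feature": feature, "value": value,
                     "went": branch, "threshold": t,
                     "branch_range": node.get(f"{branch}_range")}
                )
            else:
                raise ValueError(f"unknown node type {ntype!r} at {node_id}")

            if "note" in node:
                result.notes.append(f"couplet {couplet}: {node['note']}")
            target = node[branch]
            if "taxon" in target:
                result.taxon = target["taxon"]
                return result
            node_id = str(target["node"])


def load_default_key() -> Key:
    """The bundled key for the species-group."""
    text = (
        resources.files("numobat") / "keys" / "key_nylanderi_group.json"
    ).read_text()
    return Key(json.loads(text))


@dataclass
class FunctionClassification:
    function_id: str
    score: float
    taxon: str | None
    level: str
    in_band: bool | None
    band_group: str | None
    atypical: bool
    tie: bool = False


class PrintedFunctionRegistry:
    """Registry of the published discriminant functions and score stats."""

    def __init__(self, data: Mapping):
        self.entries: dict[str, dict] = {e["id"]: e for e in data["functions"]}

    @classmethod
    def default(cls) -> "PrintedFunctionRegistry":
        text = (
            resources.files("numobat") / "keys" / "printed_functions.json"
        ).read_text()
        return cls(json.loads(text))

    def __iter__(self):
        return iter(self.entries.values())

    def __contains__(self, function_id: str) -> bool:
        return function_id in self.entries

    def entry(self, function_id: str) -> dict:
        try:
            return self.entries[function_id]
        except KeyError:
            raise KeyError(
                f"unknown function id {function_id!r}; known ids: "
                f"{', '.join(sorted(self.entries))}"
            ) from None

    def function(self, function_id: str) -> DiscriminantFunction:
        """The registry entry as a DiscriminantFunction (linear kind only)."""
        e = self.entry(function_id)
        if e["kind"] != "linear":
            raise ValueError(f"{function_id} is a simple ratio, not linear")
        return DiscriminantFunction(
            id=e["id"],
            terms=tuple((t, float(c)) for t, c in e["terms"]),
            intercept=float(e["intercept"]),
            negative_class=e["negative_class"],
            positive_class=e["positive_class"],
            stats=e.get("groups", {}),
            source=e.get("source", ""),
            kind="linear",
        )

    def evaluate(self, function_id: str, traits: Mapping[str, float]) -> float:
        """Score of a printed function on one trait vector (μm)."""
        e = self.entry(function_id)
        if e["kind"] == "ratio":
            num, den = e["feature"].split("/")
            for t in (num, den):
                if t not in traits:
                    raise KeyError(f"{function_id}: missing trait {t}")
            return float(traits[num]) / float(traits[den])
        return self.function(function_id).evaluate(traits)

    def _side_groups(self, e: dict, side: str) -> list[str]:
        pooled = e.get(f"pooled_{side}")
        return pooled if pooled else [e[f"{side}_class"]]

    def classify(
        self,
        function_id: str,
        traits: Mapping[str, float],
        level: str = "individual",
    ) -> FunctionClassification:
        """Assign a taxon by score sign and check the published band.

        Linear functions: negative score → negative class, positive →
        positive class, exactly zero → tie.  The FRS/SL ratio entry
        classifies by the nearer published group mean.  ``in_band``
        reports whether the score falls inside the 5–95% percentile
        band (or, where no percentiles were published, the full range)
        of some group on the assigned side; a score outside every
        published band is flagged atypical.
        """
        e = self.entry(function_id)
        score = self.evaluate(function_id, traits)
        groups = e.get("groups", {})

        if e["kind"] == "ratio":
            m_neg = groups[e["negative_class"]][level]["mean"]
            m_pos = groups[e["positive_class"]][level]["mean"]
            d_neg, d_pos = abs(score - m_neg), abs(score - m_pos)
            if d_neg == d_pos:
                side = None
            else:
                side = "negative" if d_neg < d_pos else "positive"
        elif score < 0:
            side = "negative"
        elif score > 0:
            side = "positive"
        else:
            side = None

        if side is None:
            return FunctionClassification(
                function_id=function_id, score=score, taxon=None, level=level,
                in_band=None, band_group=None, atypical=False, tie=True,
            )

        def band_of(group: str):
            stats = groups.get(group, {}).get(level)
            if stats is None:
                return None
            lo = stats.get("p5", stats.get("min"))
            hi = stats.get("p95", stats.get("max"))
            return (lo, hi)

        in_band, band_group = False, None
        for g in self._side_groups(e, side):
            band = band_of(g)
            if band and band[0] <= score <= band[1]:
                in_band, band_group = True, g
                break
        atypical = not in_band
        if atypical:
            other = "positive" if side == "negative" else "negative"
            for g in self._side_groups(e, other):
                band = band_of(g)
                if band and band[0] <= score <= band[1]:
                    atypical = False  # inside the other side's band only
                    break
        return FunctionClassification(
            function_id=function_id,
            score=score,
            taxon=e[f"{side}_class"],
            level=level,
            in_band=in_band,
            band_group=band_group,
            atypical=atypical,
        )


# Module-level conveniences over the bundled artifacts -----------------

_DEFAULT_KEY: Key | None = None
_DEFAULT_REGISTRY: PrintedFunctionRegistry | None = None


def _default_key() -> Key:
    global _DEFAULT_KEY
    if _DEFAULT_KEY is None:
        _DEFAULT_KEY = load_default_key()
    return _DEFAULT_KEY


def load_registry() -> PrintedFunctionRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = PrintedFunctionRegistry.default()
    return _DEFAULT_REGISTRY


def evaluate_printed(function_id: str, traits: Mapping[str, float]) -> float:
    return load_registry().evaluate(function_id, traits)


def classify_by_function(
    function_id: str, traits: Mapping[str, float], level: str = "individual"
) -> FunctionClassification:
    return load_registry().classify(function_id, traits, level=level)


def classify_key(
    ratios: RatioVector | Mapping[str, float],
    antennomere_count: int | None = None,
    spine_angle_deg: float | None = None,
    region: Region | str | None = None,
    *,
    single_specimen: bool = False,
    key: Key | None = None,
) -> KeyResult:
    return (key or _default_key()).classify(
        ratios,
        antennomere_count=antennomere_count,
        spine_angle_deg=spine_angle_deg,
        region=region,
        single_specimen=single_specimen,
    )
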