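"""Activity catalog: MET values per activity and the occupation effort scale.

The default catalog ships as a YAML data file (``data/catalog.yaml``) so an
alternative MET compendium can be swapped in without touching code.  Each
activity is keyed by a stable snake-case ``activity_id`` used as the join key
between questionnaire responses and MET values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

DOMAINS = ("occupation", "transportation", "leisure", "sport")

__all__ = [
    "DOMAINS",
    "ActivityDefinition",
    "Catalog",
    "CatalogError",
    "load_catalog",
    "default_catalog",
    "dump_catalog",
]


class CatalogError(ValueError):
    """Raised for malformed catalog sources or failed lookups."""


@dataclass(frozen=True)
class ActivityDefinition:
    """One catalog entry binding an activity to a domain and a MET value."""

    activity_id: str
    label: str
    domain: str
    met: float

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise CatalogError(
                f"activity {self.activity_id!r}: domain {self.domain!r} "
                f"not one of {DOMAINS}"
            )
        if not self.met > 0:
            raise CatalogError(
                f"activity {self.activity_id!r}: met must be > 0, got {self.met}"
            )


@dataclass(frozen=True)
class Catalog:
    """A set of activity definitions plus the 5-rank occupation effort scale."""

    entries: tuple[ActivityDefinition, ...]
    occupation_scale: Mapping[int, float]
    _by_id: Mapping[str, ActivityDefinition] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        by_id: dict[str, ActivityDefinition] = {}
        for entry in self.entries:
            if entry.activity_id in by_id:
                raise CatalogError(f"duplicate activity_id {entry.activity_id!r}")
            by_id[entry.activity_id] = entry
        scale = dict(self.occupation_scale)
        if sorted(scale) != [1, 2, 3, 4, 5]:
            raise CatalogError(
                f"occupation_scale must map ranks 1..5, got {sorted(scale)}"
            )
        mets = [scale[r] for r in range(1, 6)]
        if any(b <= a for a, b in zip(mets, mets[1:])):
            raise CatalogError("occupation_scale METs must be strictly increasing")
        if any(m <= 0 for m in mets):
            raise CatalogError("occupation_scale METs must be positive")
        object.__setattr__(self, "occupation_scale", scale)
        object.__setattr__(self, "_by_id", by_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, activity_id: str) -> bool:
        return activity_id in self._by_id

    def activity_ids(self) -> tuple[str, ...]:
        return tuple(self._by_id)

    def entry(self, activity_id: str) -> ActivityDefinition:
        try:
            return self._by_id[activity_id]
        except KeyError:
            known = ", ".join(sorted(self._by_id))
            raise CatalogError(
                f"unknown activity_id {activity_id!r}; known ids: {known}"
            ) from None

    def domain_of(self, activity_id: str) -> str:
        return self.entry(activity_id).domain

    def by_domain(self, domain: str) -> tuple[ActivityDefinition, ...]:
        return tuple(e for e in self.entries if e.domain == domain)


def lookup_met(catalog: Catalog, activity_id: str) -> float:
    """Return the MET value for ``activity_id``.

    Raises :class:`CatalogError` listing the known ids if absent.
    """
    return catalog.entry(activity_id).met


def occupation_met(catalog: Catalog, effort_rank: int) -> float:
    """MET for an occupation effort rank on the 1..5 scale."""
    if effort_rank not in catalog.occupation_scale:
        raise CatalogError(f"occupation effort rank must be in 1..5, got {effort_rank}")
    return catalog.occupation_scale[effort_rank]


def _parse_entry(raw: object) -> ActivityDefinition:
    if not isinstance(raw, Mapping):
        raise CatalogError(f"malformed catalog entry (not a mapping): {raw!r}")
    missing = {"activity_id", "label", "domain", "met"} - set(raw)
    if missing:
        raise CatalogError(
            f"malformed catalog entry {raw.get('activity_id', raw)!r}: "
            f"missing fields {sorted(missing)}"
        )
    try:
        met = float(raw["met"])
    except (TypeError, ValueError):
        raise CatalogError(
            f"entry {raw['activity_id']!r}: met is not numeric: {raw['met']!r}"
        ) from None
    return ActivityDefinition(
        activity_id=str(raw["activity_id"]),
        label=str(raw["label"]),
        domain=str(raw["domain"]),
        met=met,
    )


def load_catalog(source: str | io.TextIOBase | None = None) -> Catalog:
    """Parse a YAML catalog; with ``source=None`` load the built-in default.

    The document must hold an ``activities`` list (activity_id, label,
    domain, met per item) and a 5-entry ``occupation_scale`` mapping.
    """
    if source is None:
        text = (
            resources.files("activeq").joinpath("data/catalog.yaml").read_text()
        )
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "activities" not in doc:
        raise CatalogError("catalog source must be a mapping with an 'activities' list")
    entries = tuple(_parse_entry(raw) for raw in doc["activities"])
    scale_raw = doc.get("occupation_scale", {})
    try:
        scale = {int(k): float(v) for k, v in scale_raw.items()}
    except (TypeError, ValueError, AttributeError):
        raise CatalogError(f"malformed occupation_scale: {scale_raw!r}") from None
    return Catalog(entries=entries, occupation_scale=scale)


def dump_catalog(catalog: Catalog) -> str:
    """Serialize a catalog back to YAML text (round-trips with load_catalog)."""
    doc = {
        "occupation_scale": {r: catalog.occupation_scale[r] for r in range(1, 6)},
        "activities": [
            {
                "activity_id": e.activity_id,
                "label": e.label,
                "domain": e.domain,
                "met": e.met,
            }
            for e in catalog.entries
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def default_catalog() -> Catalog:
    """The built-in catalog shipped with the package."""
    return load_catalog(None)
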