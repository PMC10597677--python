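"""Fatty-acid shorthand notation and the desaturation–elongation reaction network.

Fatty acids are represented canonically as ``(carbons, double_bonds, omega)``
with Δ positions always derived under the methylene-interrupted rule, so
inconsistent bond placements cannot be constructed.  Enzyme activities
(front-end desaturation, methyl-end desaturation, elongation, β-oxidative
shortening) act on this representation, and :func:`reachable_set` computes the
breadth-first closure of a precursor pool under an activity set.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FattyAcid",
    "ActivityKind",
    "EnzymeActivity",
    "FattyAcidError",
    "ParseError",
    "ValidationError",
    "InapplicableReactionError",
    "parse_fatty_acid",
    "delta_positions",
    "apply_front_end_desaturation",
    "apply_methyl_end_desaturation",
    "apply_elongation",
    "apply_beta_oxidation_shortening",
    "reachable_set",
    "PathwayClosure",
    "close_pathway",
    "load_activity_preset",
    "activities_from_config",
    "BDELLOID_CHARACTERIZED",
]


class FattyAcidError(Exception):
    """Base class for fatty-acid domain errors."""


class ParseError(FattyAcidError, ValueError):
    """Shorthand string does not match ``C:Dn-W``."""


class ValidationError(FattyAcidError, ValueError):
    """Field combination violates the fatty-acid invariants."""


class InapplicableReactionError(FattyAcidError):
    """An enzyme operation's precondition does not hold for the substrate."""


_VALID_OMEGA = frozenset({3, 6, 9})


@dataclass(frozen=True, order=True)
class FattyAcid:
    """A methylene-interrupted fatty acid in ``C:Dn-W`` shorthand.

    Parameters
    ----------
    carbons
        Chain length; even and ≥ 4.
    double_bonds
        Number of double bonds, ≥ 0.
    omega
        Position of the terminal (distal-most) double bond counted from the
        methyl end; one of 3, 6 or 9, or ``None`` for saturated acids.
    """

    carbons: int
    double_bonds: int
    omega: int | None = None

    def __post_init__(self) -> None:
        if self.carbons < 4 or self.carbons % 2 != 0:
            raise ValidationError(f"carbons must be even and >= 4, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValidationError("double_bonds must be >= 0")
        if self.double_bonds == 0:
            if self.omega is not None:
                raise ValidationError("saturated acid cannot carry an omega class")
        else:
            if self.omega is None:
                raise ValidationError("unsaturated acid requires an omega class")
            if self.omega not in _VALID_OMEGA:
                raise ValidationError(f"omega must be one of {sorted(_VALID_OMEGA)}")
            # proximal bond position must leave >= 2 carbons to the carboxyl end
            if self.carbons - self.omega - 3 * (self.double_bonds - 1) < 2:
                raise ValidationError(
                    f"{self.carbons}:{self.double_bonds}n-{self.omega} cannot fit "
                    f"{self.double_bonds} methylene-interrupted double bonds"
                )

    @property
    def saturated(self) -> bool:
        return self.double_bonds == 0

    def __str__(self) -> str:
        if self.saturated:
            return f"{self.carbons}:0"
        return f"{self.carbons}:{self.double_bonds}n-{self.omega}"


_SHORTHAND_RE = re.compile(
    r"^\s*(\d+)\s*:\s*(\d+)\s*(?:n\s*-\s*(\d+)\s*)?$"
)


def parse_fatty_acid(notation: str) -> FattyAcid:
    """Parse shorthand like ``"20:5n-3"`` or ``"18 : 0"`` into a :class:`FattyAcid`.

    Raises :class:`ParseError` for malformed strings and
    :class:`ValidationError` for well-formed but infeasible combinations.
    """
    m = _SHORTHAND_RE.match(notation)
    if m is None:
        raise ParseError(f"cannot parse fatty-acid shorthand {notation!r}")
    carbons, double_bonds = int(m.group(1)), int(m.group(2))
    omega = int(m.group(3)) if m.group(3) is not None else None
    return FattyAcid(carbons, double_bonds, omega)


def delta_positions(fa: FattyAcid) -> list[int]:
    """Double-bond Δ positions counted from the carboxyl terminus, ascending.

    Under methylene interruption the distal bond sits at ``carbons - omega``
    and each further bond lies 3 carbons closer to the carboxyl end.
    """
    if fa.saturated:
        return []
    assert fa.omega is not None
    distal = fa.carbons - fa.omega
    return [distal - 3 * k for k in range(fa.double_bonds - 1, -1, -1)]


def apply_front_end_desaturation(fa: FattyAcid, delta: int) -> FattyAcid:
    """Insert a bond at Δ ``delta``, between the proximal bond and the carboxyl end.

    Requires the substrate's proximal (smallest-Δ) bond to sit at
    ``delta + 3`` so the product stays methylene-interrupted.
    """
    positions = delta_positions(fa)
    if not positions or min(positions) != delta + 3:
        raise InapplicableReactionError(
            f"Δ{delta} front-end desaturation inapplicable to {fa}: "
            f"needs an existing proximal bond at Δ{delta + 3}"
        )
    return FattyAcid(fa.carbons, fa.double_bonds + 1, fa.omega)


def apply_methyl_end_desaturation(fa: FattyAcid, delta: int) -> FattyAcid:
    """Insert a bond at Δ ``delta`` distal to the current distal-most bond.

    Requires the distal bond at ``delta - 3`` and a product omega class
    (``carbons - delta``) of 3 or 6.
    """
    positions = delta_positions(fa)
    new_omega = fa.carbons - delta
    if not positions or max(positions) != delta - 3:
        raise InapplicableReactionError(
            f"Δ{delta} methyl-end desaturation inapplicable to {fa}: "
            f"needs the distal bond at Δ{delta - 3}"
        )
    if new_omega not in (3, 6):
        raise InapplicableReactionError(
            f"Δ{delta} methyl-end desaturation on {fa} would give omega {new_omega}, "
            "outside {3, 6}"
        )
    return FattyAcid(fa.carbons, fa.double_bonds + 1, new_omega)


def apply_elongation(fa: FattyAcid) -> FattyAcid:
    """Extend the chain by two carbons; every Δ position shifts by +2."""
    return FattyAcid(fa.carbons + 2, fa.double_bonds, fa.omega)


def apply_beta_oxidation_shortening(fa: FattyAcid) -> FattyAcid:
    """Remove two carbons from the carboxyl end (one β-oxidation round).

    Requires the proximal bond at Δ ≥ 6 so the product's proximal bond stays
    at Δ ≥ 4.
    """
    positions = delta_positions(fa)
    if not positions:
        raise InapplicableReactionError(f"shortening of saturated {fa} not modelled")
    if min(positions) < 6:
        raise InapplicableReactionError(
            f"shortening {fa} would push its proximal bond below Δ4"
        )
    return FattyAcid(fa.carbons - 2, fa.double_bonds, fa.omega)


class ActivityKind(str, Enum):
    FRONT_END_DESATURATION = "front_end_desaturation"
    METHYL_END_DESATURATION = "methyl_end_desaturation"
    ELONGATION = "elongation"
    BETA_OXIDATION_SHORTENING = "beta_oxidation_shortening"


@dataclass(frozen=True)
class EnzymeActivity:
    """One enzymatic capability applicable to fatty acids.

    ``delta`` is set for desaturations only; ``substrate_carbons`` restricts
    elongation to admissible chain lengths and must then be non-empty.
    """

    kind: ActivityKind
    delta: int | None = None
    substrate_carbons: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        kind = ActivityKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "substrate_carbons", frozenset(self.substrate_carbons))
        if kind in (ActivityKind.FRONT_END_DESATURATION, ActivityKind.METHYL_END_DESATURATION):
            if self.delta is None:
                raise ValidationError(f"{kind.value} requires a delta position")
            if kind is ActivityKind.FRONT_END_DESATURATION and self.delta < 4:
                raise ValidationError("front-end desaturation requires delta >= 4")
        if kind is ActivityKind.ELONGATION and not self.substrate_carbons:
            raise ValidationError("elongation requires a non-empty substrate carbon range")

    def label(self) -> str:
        if self.kind is ActivityKind.FRONT_END_DESATURATION:
            return f"Fed_d{self.delta}"
        if self.kind is ActivityKind.METHYL_END_DESATURATION:
            return f"wx_d{self.delta}"
        if self.kind is ActivityKind.ELONGATION:
            rng = "+".join(f"C{c}" for c in sorted(self.substrate_carbons))
            return f"Elo_{rng}"
        return "shortening"

    def apply(self, fa: FattyAcid) -> FattyAcid:
        """Apply this activity to ``fa`` or raise :class:`InapplicableReactionError`."""
        if self.kind is ActivityKind.FRONT_END_DESATURATION:
            assert self.delta is not None
            return apply_front_end_desaturation(fa, self.delta)
        if self.kind is ActivityKind.METHYL_END_DESATURATION:
            assert self.delta is not None
            return apply_methyl_end_desaturation(fa, self.delta)
        if self.kind is ActivityKind.ELONGATION:
            if fa.carbons not in self.substrate_carbons:
                raise InapplicableReactionError(
                    f"elongation substrate range {sorted(self.substrate_carbons)} "
                    f"excludes C{fa.carbons}"
                )
            return apply_elongation(fa)
        return apply_beta_oxidation_shortening(fa)


# Characterized bdelloid activity set: dual Δ12/Δ15 methyl-end desaturases,
# Δ6 and Δ5 front-end desaturases, and an elongase active on C18 and C20
# (but not C22) substrates.
BDELLOID_CHARACTERIZED: tuple[EnzymeActivity, ...] = (
    EnzymeActivity(ActivityKind.METHYL_END_DESATURATION, delta=12),
    EnzymeActivity(ActivityKind.METHYL_END_DESATURATION, delta=15),
    EnzymeActivity(ActivityKind.FRONT_END_DESATURATION, delta=6),
    EnzymeActivity(ActivityKind.FRONT_END_DESATURATION, delta=5),
    EnzymeActivity(ActivityKind.ELONGATION, substrate_carbons=frozenset({18, 20})),
)


def activities_from_config(entries: Iterable[Mapping]) -> list[EnzymeActivity]:
    """Build activities from config dicts ``{kind, delta?, substrate_carbons?}``."""
    out = []
    for entry in entries:
        out.append(
            EnzymeActivity(
                kind=ActivityKind(entry["kind"]),
                delta=entry.get("delta"),
                substrate_carbons=frozenset(entry.get("substrate_carbons", ())),
            )
        )
    return out


def load_activity_preset(name_or_path: str) -> list[EnzymeActivity]:
    """Load an activity set from a bundled preset name or a JSON file path.

    The JSON layout is ``{"activities": [{"kind": ..., "delta": ...,
    "substrate_carbons": [...]}, ...]}`` or a bare list of such dicts.
    """
    presets = json.loads(
        resources.files("pufascreen.data").joinpath("activity_presets.json").read_text()
    )
    if name_or_path in presets:
        return activities_from_config(presets[name_or_path]["activities"])
    with open(name_or_path) as fh:
        doc = json.load(fh)
    entries = doc["activities"] if isinstance(doc, dict) else doc
    return activities_from_config(entries)


@dataclass
class PathwayClosure:
    """Reachability closure with predecessor links for path reconstruction."""

    acids: set[FattyAcid]
    predecessor: dict[FattyAcid, tuple[FattyAcid, EnzymeActivity] | None]

    def path(self, target: FattyAcid) -> list[tuple[FattyAcid, EnzymeActivity | None]]:
        """Reaction path from a precursor to ``target`` as (acid, producing activity).

        The first element carries ``None`` as its producing activity.
        Raises ``KeyError`` if the target is unreachable.
        """
        if target not in self.predecessor:
            raise KeyError(f"{target} is not reachable")
        steps: list[tuple[FattyAcid, EnzymeActivity | None]] = []
        node: FattyAcid | None = target
        while node is not None:
            link = self.predecessor[node]
            steps.append((node, link[1] if link else None))
            node = link[0] if link else None
        steps.reverse()
        return steps


def close_pathway(
    activities: Sequence[EnzymeActivity],
    precursors: Iterable[FattyAcid],
    max_carbons: int = 24,
) -> PathwayClosure:
    """Breadth-first closure of ``precursors`` under ``activities``.

    Products longer than ``max_carbons`` are pruned.  Frontier expansion order
    is fixed by sorting acids on (carbons, double_bonds, omega), and activities
    are tried in their given order, so predecessor links are deterministic.
    """
    start = sorted(set(precursors))
    predecessor: dict[FattyAcid, tuple[FattyAcid, EnzymeActivity] | None] = {
        fa: None for fa in start
    }
    frontier = list(start)
    while frontier:
        frontier.sort()
        next_frontier: list[FattyAcid] = []
        for fa in frontier:
            for act in activities:
                try:
                    product = act.apply(fa)
                except FattyAcidError:
                    continue
                if product.carbons > max_carbons or product in predecessor:
                    continue
                predecessor[product] = (fa, act)
                next_frontier.append(product)
        frontier = next_frontier
    return PathwayClosure(set(predecessor), predecessor)


def reachable_set(
    activities: Sequence[EnzymeActivity],
    precursors: Iterable[FattyAcid],
    max_carbons: int = 24,
) -> set[FattyAcid]:
    """Set of fatty acids reachable from ``precursors`` under ``activities``."""
    return close_pathway(activities, precursors, max_carbons).acids
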