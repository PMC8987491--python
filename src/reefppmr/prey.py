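"""Prey-item processing: length-to-mass conversion, measurement filters,
biomass weights.

Gut-content prey are measured as lengths (longest body axis, mm) and
converted to wet mass through per-taxon allometries ``mass = a * length^b``.
Conversions published as length -> dry mass carry a dry-to-wet factor.
Below-threshold prey (0.5 mm for planktivore predators, 1 mm for all other
guilds) are not measured in the field protocol the data emulate, so they are
filtered out before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

GUILDS = ("herbivore", "invertivore", "planktivore", "piscivore")

#: Minimum measurable prey length (mm) per predator guild; comparisons are
#: strict (> threshold retained).
MIN_PREY_LENGTH_MM = {
    "herbivore": 1.0,
    "invertivore": 1.0,
    "planktivore": 0.5,
    "piscivore": 1.0,
}

#: Placeholder dry-to-wet multiplier used when a dry-weight allometry has no
#: factor supplied.  Dry mass is roughly 20% of wet mass in soft-bodied
#: invertebrates, hence wet ~ 5 x dry.
DEFAULT_DRY_TO_WET_FACTOR = 5.0


@dataclass
class PreyItem:
    """One measured prey item from a predator's gut."""

    prey_id: str
    predator_id: str
    taxon: str
    length_mm: float
    wet_mass_g: float | None = None
    weight: float = 0.0


@dataclass
class AllometryRule:
    """Length-weight conversion for one prey taxon: mass = a * length^b."""

    taxon: str
    a: float
    b: float
    length_unit: str = "mm"  # unit the coefficients expect
    dry_flag: bool = False
    dry_to_wet_factor: float = 1.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("allometry coefficients a, b must be positive")
        if self.dry_to_wet_factor <= 0:
            raise ValueError("dry_to_wet_factor must be positive")
        if self.length_unit not in ("mm", "cm"):
            raise ValueError(f"unsupported length unit {self.length_unit!r}")


class MissingAllometryError(KeyError):
    """No length-weight rule for a prey taxon."""


def rules_from_frame(table: pd.DataFrame) -> dict[str, AllometryRule]:
    """Build a taxon -> rule mapping from an allometry table."""
    rules = {}
    for row in table.itertuples(index=False):
        dry = bool(row.dry_flag)
        factor = float(getattr(row, "dry_to_wet_factor", np.nan))
        if dry and not np.isfinite(factor):
            warnings.warn(
                f"taxon {row.taxon!r}: dry-weight allometry without a "
                f"dry-to-wet factor; using placeholder "
                f"{DEFAULT_DRY_TO_WET_FACTOR}",
                stacklevel=2,
            )
            factor = DEFAULT_DRY_TO_WET_FACTOR
        rules[str(row.taxon)] = AllometryRule(
            taxon=str(row.taxon),
            a=float(row.a),
            b=float(row.b),
            length_unit=str(row.length_unit),
            dry_flag=dry,
            dry_to_wet_factor=factor if dry else 1.0,
        )
    return rules


def convert_length_to_mass(item: PreyItem, rule: AllometryRule) -> PreyItem:
    """Convert a prey item's length (mm) to wet mass (g).

    ``mass = a * length^b`` in the rule's length unit; when the rule yields
    dry mass, the configured dry-to-wet factor multiplies the result.
    """
    if rule is None:
        raise MissingAllometryError(
            f"no length-weight rule for taxon {item.taxon!r}"
        )
    if item.length_mm is None or item.length_mm <= 0:
        raise ValueError(
            f"prey {item.prey_id}: length must be positive, "
            f"got {item.length_mm!r}"
        )
    length = item.length_mm if rule.length_unit == "mm" else item.length_mm / 10.0
    mass = rule.a * length**rule.b
    if rule.dry_flag:
        mass *= rule.dry_to_wet_factor
    return replace(item, wet_mass_g=float(mass))


def convert_batch(
    items: list[PreyItem], rules: dict[str, AllometryRule]
) -> list[PreyItem]:
    """Convert many prey items, raising on the first missing taxon."""
    out = []
    for it in items:
        rule = rules.get(it.taxon)
        if rule is None:
            raise MissingAllometryError(
                f"no length-weight rule for taxon {it.taxon!r}"
            )
        out.append(convert_length_to_mass(it, rule))
    return out


def apply_min_size_filter(
    items: list[PreyItem], guild: str
) -> tuple[list[PreyItem], int]:
    """Drop prey at or below the guild's minimum measurable length.

    Retention is strict: a prey is kept iff ``length_mm > threshold``
    (0.5 mm for planktivores, 1 mm otherwise).  Returns the retained items
    and the number removed.  Idempotent.
    """
    if guild not in MIN_PREY_LENGTH_MM:
        raise ValueError(f"unknown guild {guild!r}; expected one of {GUILDS}")
    thr = MIN_PREY_LENGTH_MM[guild]
    kept = [it for it in items if it.length_mm > thr]
    return kept, len(items) - len(kept)


def compute_biomass_weights(
    items: list[PreyItem], scheme: str = "normalized"
) -> list[PreyItem]:
    """Assign biomass weights to the prey of a single predator.

    ``raw``: weight = wet mass (g); ``normalized`` (default): weight =
    wet mass / total wet mass within the predator (sums to 1).  The
    normalized scheme keeps the biomass-weighting interpretation (large prey
    dominate within a gut) while giving every predator the same total
    weight, so guilds with small-bodied prey are not drowned out of the
    cross-guild fit by the gram scale of large-prey guilds.
    """
    if scheme not in ("raw", "normalized"):
        raise ValueError("scheme must be 'raw' or 'normalized'")
    masses = np.array([it.wet_mass_g for it in items], dtype=float)
    if len(items) == 0:
        return []
    if np.any(~np.isfinite(masses)) or np.any(masses < 0):
        raise ValueError("all prey masses must be computed and non-negative")
    if scheme == "normalized":
        total = masses.sum()
        if total <= 0:
            raise ValueError("cannot normalize weights: total prey mass is 0")
        weights = masses / total
    else:
        if masses.sum() <= 0:
            raise ValueError("all-zero prey masses; weights undefined")
        weights = masses
    return [replace(it, weight=float(wt)) for it, wt in zip(items, weights)]


def process_gut_frame(
    gut: pd.DataFrame,
    allometry: pd.DataFrame,
    scheme: str = "normalized",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full prey-processing pass over a gut-content table.

    Converts lengths to wet mass, applies the per-guild minimum-size filter,
    and computes biomass weights within each predator.  Returns the processed
    table and an audit table of dropped rows with reason codes.
    """
    rules = rules_from_frame(allometry)
    rows, audit = [], []
    for (pred_id, guild), grp in gut.groupby(
        ["predator_id", "guild"], sort=False
    ):
        items = [
            PreyItem(
                prey_id=f"{pred_id}_{i}",
                predator_id=str(pred_id),
                taxon=str(r.prey_taxon),
                length_mm=float(r.prey_length_mm),
            )
            for i, r in enumerate(grp.itertuples(index=False))
        ]
        items = convert_batch(items, rules)
        kept, n_removed = apply_min_size_filter(items, guild)
        for it in items:
            if it not in kept:
                audit.append(
                    {
                        "prey_id": it.prey_id,
                        "predator_id": pred_id,
                        "reason": "below_min_length",
                        "length_mm": it.length_mm,
                    }
                )
        if not kept:
            audit.append(
                {
                    "prey_id": "",
                    "predator_id": pred_id,
                    "reason": "no_measurable_prey",
                    "length_mm": np.nan,
                }
            )
            continue
        kept = compute_biomass_weights(kept, scheme=scheme)
        base = grp.iloc[0]
        for it in kept:
            rows.append(
                {
                    "predator_id": pred_id,
                    "species": base["species"],
                    "genus": base["genus"],
                    "guild": guild,
                    "predator_mass_g": float(base["predator_mass_g"]),
                    "prey_taxon": it.taxon,
                    "prey_length_mm": it.length_mm,
                    "wet_mass_g": it.wet_mass_g,
                    "weight": it.weight,
                }
            )
    processed = pd.DataFrame(rows)
    audit_df = pd.DataFrame(
        audit, columns=["prey_id", "predator_id", "reason", "length_mm"]
    )
    return processed, audit_df
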