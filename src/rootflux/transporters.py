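"""Carrier localization rules and genotype modification.

Encodes where the ABCB efflux transporters (ABCB1/4/19, nonpolar within a
cell), the PIN efflux carriers (polar) and the AUX1/LAX influx carriers sit
on the membranes of each cell type, plus plasmodesmatal permeabilities per
cell-cell interface.  All placements are driven by editable rule tables so
alternative localization hypotheses can be tested without code changes.

Rules follow the root-tip conventions of the vertex-based auxin transport
model lineage: ABCB1+ABCB19 throughout the inner tissues, ABCB4 alone in the
epidermis / outer LRC / outermost columella tier, PIN rootward in the stele
side and shootward through the outer layers, AUX1/LAX in the cap, epidermis
and stele.  PIN and influx entries record which family member motivates them
(provenance), and counts are the number of members present.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .geometry import RootTemplate, is_cap_type

ALL_FACES = ("rootward", "shootward", "inner_lateral", "outer_lateral")

ABCB_NAMES = ("ABCB1", "ABCB4", "ABCB19")


class TransporterError(ValueError):
    pass


@dataclass
class CarrierCounts:
    """Carrier content of one membrane segment.

    ABCB counts are scalars; PIN and influx carriers are member -> count maps
    so that knockouts of a single family member (e.g. *pin2*) can be applied.
    """

    abcb1: float = 0.0
    abcb4: float = 0.0
    abcb19: float = 0.0
    pins: dict[str, float] = field(default_factory=dict)
    influx: dict[str, float] = field(default_factory=dict)

    @property
    def n_pin(self) -> float:
        return float(sum(self.pins.values()))

    @property
    def aux_influx_weight(self) -> float:
        return float(sum(self.influx.values()))

    def abcb_total(self, include_abcb4: bool = True) -> float:
        return self.abcb1 + self.abcb19 + (self.abcb4 if include_abcb4 else 0.0)

    def copy(self) -> "CarrierCounts":
        return CarrierCounts(
            self.abcb1, self.abcb4, self.abcb19, dict(self.pins), dict(self.influx)
        )


@dataclass
class TransporterDistribution:
    """Per-membrane-segment carrier counts plus per-wall PD permeability."""

    counts: dict[tuple[int, int], CarrierCounts]  # (cell_id, wall_id) -> counts
    pd_permeability: dict[int, float]  # wall_id -> um/s
    abcb4_mode: str = "efflux"  # "efflux" | "influx"

    def copy(self) -> "TransporterDistribution":
        return TransporterDistribution(
            {k: v.copy() for k, v in self.counts.items()},
            dict(self.pd_permeability),
            self.abcb4_mode,
        )


@dataclass(frozen=True)
class Genotype:
    """Knockouts plus whole-root multiplicative expression scaling.

    Carrier names: ABCB1, ABCB4, ABCB19, PIN family members (PIN1, PIN2, ...)
    and influx members (AUX1, LAX2, LAX3).  Scaling is uniform across the
    template (RT-qPCR gives whole-root fold changes, no spatial resolution).
    """

    knockouts: frozenset[str] = frozenset()
    expression_scaling: Mapping[str, float] = field(default_factory=dict)
    name: str = "WT"

    def __post_init__(self):
        overlap = set(self.knockouts) & set(self.expression_scaling)
        if overlap:
            raise TransporterError(f"carriers both knocked out and scaled: {overlap}")
        for k, v in self.expression_scaling.items():
            if v <= 0:
                raise TransporterError(f"scaling for {k} must be > 0")


WILD_TYPE = Genotype()


def genotype(spec: str) -> Genotype:
    """Parse mutant shorthand like ``"abcb1 abcb19"`` into a Genotype."""
    spec = spec.strip()
    if not spec or spec.upper() in ("WT", "COL0", "COL-0", "WILD-TYPE"):
        return WILD_TYPE
    kos = frozenset(tok.upper() for tok in spec.replace(",", " ").split())
    return Genotype(knockouts=kos, name=spec)


# ---------------------------------------------------------------------------
# Default rule tables (editable)
# ---------------------------------------------------------------------------

#: ABCBs are nonpolar: one count per cell type, placed on every face.
#: Epidermis and outer LRC carry only ABCB4 (the model-rule reading of the
#: localization data); inner columella tiers carry none.
DEFAULT_ABCB_RULES: dict[str, dict[str, float]] = {
    "stele": {"ABCB1": 1, "ABCB19": 1},
    "pericycle": {"ABCB1": 1, "ABCB19": 1},
    "endodermis": {"ABCB1": 1, "ABCB19": 1},
    "cortex": {"ABCB1": 1, "ABCB19": 1},
    "epidermis": {"ABCB4": 1},
    "LRC_outer": {"ABCB4": 1},
    "LRC_inner": {"ABCB1": 1},
    "QC": {"ABCB1": 1, "ABCB19": 1},
    "columella_outermost": {"ABCB4": 1},
    "columella_inner": {},
}

#: Polar PIN placement: rows (cell_type, zone or None=both, face or "all",
#: {member: count}).  Stele-side files drive rootward flux; the outer layers
#: drive shootward flux in the EZ; columella PINs are nonpolar.
DEFAULT_PIN_RULES: list[tuple[str, str | None, str, dict[str, float]]] = [
    ("stele", None, "rootward", {"PIN1": 1, "PIN3": 1, "PIN7": 1}),
    ("pericycle", None, "rootward", {"PIN1": 1}),
    ("endodermis", None, "rootward", {"PIN1": 1}),
    ("epidermis", "EZ", "shootward", {"PIN2": 1}),
    # cortical PIN2 flips polarity at the MZ/EZ boundary
    ("cortex", "MZ", "rootward", {"PIN2": 1}),
    ("cortex", "EZ", "shootward", {"PIN2": 1}),
    ("LRC_inner", None, "shootward", {"PIN2": 1}),
    ("LRC_outer", None, "shootward", {"PIN2": 1}),
    ("columella", None, "all", {"PIN3": 1, "PIN7": 1}),
]

#: AUX1/LAX influx carriers, apolar (all faces).
DEFAULT_INFLUX_RULES: list[tuple[str, str | None, str, dict[str, float]]] = [
    ("LRC_inner", None, "all", {"AUX1": 1}),
    ("LRC_outer", None, "all", {"AUX1": 1}),
    ("epidermis", "EZ", "all", {"AUX1": 1}),
    ("columella", None, "all", {"AUX1": 1, "LAX3": 1}),
    # phloem unloading: apolar influx carriers in the stele are confined to
    # the meristematic (protophloem) region; through the elongation zone the
    # protophloem conduit takes up auxin on the axial (shootward) faces,
    # standing in for the interior protophloem files of a resolved stele
    ("stele", "MZ", "all", {"AUX1": 1, "LAX2": 1}),
    ("stele", "EZ", "shootward", {"AUX1": 1}),
]

#: Plasmodesmatal permeability (um/s) per unordered tissue-pair interface,
#: with a catch-all default; boundary walls always get 0.  The root cap is
#: symplastically isolated from the epidermis (electron-microscopy PD counts
#: at that interface are near zero).
DEFAULT_PD_RULES: dict[frozenset[str] | str, float] = {
    "default": 0.3,
    frozenset(("LRC_inner", "epidermis")): 0.0,
    frozenset(("LRC_inner", "cortex")): 0.0,
}


def _norm_type(cell_type: str) -> str:
    if cell_type.startswith("columella_tier_"):
        return "columella"
    return cell_type


def _columella_rule_key(cell_type: str, outermost_tier: int) -> str:
    k = int(cell_type.rsplit("_", 1)[1])
    return "columella_outermost" if k == outermost_tier else "columella_inner"


def _outermost_tier(template: RootTemplate) -> int:
    tiers = [
        int(c.cell_type.rsplit("_", 1)[1])
        for c in template.cells.values()
        if c.cell_type.startswith("columella_tier_")
    ]
    return max(tiers) if tiers else 0


# ---------------------------------------------------------------------------
# Assignment operations
# ---------------------------------------------------------------------------


def _empty_distribution(template: RootTemplate) -> TransporterDistribution:
    return TransporterDistribution(
        counts={s.key: CarrierCounts() for s in template.membrane_segments},
        pd_permeability={w.id: 0.0 for w in template.walls.values()},
    )


def assign_abcbs(
    template: RootTemplate,
    dist: TransporterDistribution | None = None,
    rules: Mapping[str, Mapping[str, float]] | None = None,
) -> TransporterDistribution:
    """Place the nonpolar ABCBs: identical counts on every face of a cell."""
    rules = rules if rules is not None else DEFAULT_ABCB_RULES
    dist = dist or _empty_distribution(template)
    outer = _outermost_tier(template)
    for seg in template.membrane_segments:
        ctype = template.cells[seg.cell_id].cell_type
        if ctype.startswith("columella_tier_"):
            key = _columella_rule_key(ctype, outer)
        else:
            key = ctype
        if key not in rules:
            raise TransporterError(f"no ABCB rule for cell type {ctype!r}")
        entry = rules[key]
        c = dist.counts[seg.key]
        c.abcb1 = float(entry.get("ABCB1", 0.0))
        c.abcb4 = float(entry.get("ABCB4", 0.0))
        c.abcb19 = float(entry.get("ABCB19", 0.0))
    return dist


def _apply_polar_rules(template, dist, rules, attr):
    known = {_norm_type(c.cell_type) for c in template.cells.values()}
    rule_types = {r[0] for r in rules}
    for seg in template.membrane_segments:
        cell = template.cells[seg.cell_id]
        ntype = _norm_type(cell.cell_type)
        for r_type, r_zone, r_face, members in rules:
            if r_type != ntype:
                continue
            if r_zone is not None and cell.zone != r_zone:
                continue
            if r_face != "all" and seg.face != r_face:
                continue
            target = getattr(dist.counts[seg.key], attr)
            for m, n in members.items():
                target[m] = target.get(m, 0.0) + float(n)
    return dist


def assign_pins_and_influx(
    template: RootTemplate,
    dist: TransporterDistribution | None = None,
    pin_rules=None,
    influx_rules=None,
) -> TransporterDistribution:
    """Place the polar PINs and apolar AUX1/LAX carriers from the rule tables."""
    dist = dist or _empty_distribution(template)
    _apply_polar_rules(
        template, dist, pin_rules if pin_rules is not None else DEFAULT_PIN_RULES, "pins"
    )
    _apply_polar_rules(
        template,
        dist,
        influx_rules if influx_rules is not None else DEFAULT_INFLUX_RULES,
        "influx",
    )
    return dist


def assign_plasmodesmata(
    template: RootTemplate,
    dist: TransporterDistribution | None = None,
    rules: Mapping | None = None,
) -> TransporterDistribution:
    """Assign PD permeability per shared wall from the interface-type table.

    Boundary (outer-surface) walls get 0.  The table is keyed by frozenset of
    the two (normalized) tissue names with a ``"default"`` fallback.
    """
    rules = rules if rules is not None else DEFAULT_PD_RULES
    dist = dist or _empty_distribution(template)
    for w in template.walls.values():
        if w.is_boundary:
            dist.pd_permeability[w.id] = 0.0
            continue
        a, b = (_norm_type(template.cells[cid].cell_type) for cid in w.cell_ids)
        key = frozenset((a, b))
        dist.pd_permeability[w.id] = float(rules.get(key, rules.get("default", 0.0)))
    return dist


def build_distribution(
    template: RootTemplate,
    abcb_rules=None,
    pin_rules=None,
    influx_rules=None,
    pd_rules=None,
) -> TransporterDistribution:
    """Convenience: ABCBs + PINs/influx + plasmodesmata in one call."""
    dist = _empty_distribution(template)
    assign_abcbs(template, dist, abcb_rules)
    assign_pins_and_influx(template, dist, pin_rules, influx_rules)
    assign_plasmodesmata(template, dist, pd_rules)
    return dist


# ---------------------------------------------------------------------------
# Genotypes and the ABCB4 transport-direction variant
# ---------------------------------------------------------------------------

_ABCB_ATTR = {"ABCB1": "abcb1", "ABCB4": "abcb4", "ABCB19": "abcb19"}


def apply_genotype(
    dist: TransporterDistribution, geno: Genotype
) -> TransporterDistribution:
    """Zero out knocked-out carriers and scale the rest, uniformly.

    Idempotent for pure knockouts; composing single knockouts equals applying
    the combined genotype.
    """
    known = set(_ABCB_ATTR)
    for c in dist.counts.values():
        known |= set(c.pins) | set(c.influx)
    unknown = (set(geno.knockouts) | set(geno.expression_scaling)) - known
    if unknown:
        raise TransporterError(f"unknown carrier name(s): {sorted(unknown)}")

    out = dist.copy()
    for c in out.counts.values():
        for name, attr in _ABCB_ATTR.items():
            if name in geno.knockouts:
                setattr(c, attr, 0.0)
            elif name in geno.expression_scaling:
                setattr(c, attr, getattr(c, attr) * geno.expression_scaling[name])
        for table in (c.pins, c.influx):
            for member in list(table):
                if member in geno.knockouts:
                    table[member] = 0.0
                elif member in geno.expression_scaling:
                    table[member] *= geno.expression_scaling[member]
    return out


def set_abcb4_mode(dist: TransporterDistribution, mode: str) -> TransporterDistribution:
    """Switch ABCB4 between efflux (default) and influx operation.

    In influx mode each segment's ABCB4 count moves to the influx side (one
    unit of influx weight per ABCB4, matching the AUX1/LAX weighting) and
    contributes nothing to efflux, including the co-dependent product.
    """
    if mode not in ("efflux", "influx"):
        raise TransporterError(f"abcb4_mode must be 'efflux' or 'influx', got {mode!r}")
    out = dist.copy()
    if mode == "influx" and out.abcb4_mode == "efflux":
        for c in out.counts.values():
            if c.abcb4:
                c.influx["ABCB4"] = c.influx.get("ABCB4", 0.0) + c.abcb4
                c.abcb4 = 0.0
    elif mode == "efflux" and out.abcb4_mode == "influx":
        for c in out.counts.values():
            moved = c.influx.pop("ABCB4", 0.0)
            c.abcb4 += moved
    out.abcb4_mode = mode
    return out


# ---------------------------------------------------------------------------
# YAML rule-table / genotype loading
# ---------------------------------------------------------------------------


def load_rules(path) -> dict:
    """Load rule tables from YAML.

    Recognized top-level keys: ``abcb`` (cell_type -> {carrier: count}),
    ``pin`` / ``influx`` (lists of {cell_type, zone, face, members}), and
    ``pd`` ({"tissueA|tissueB": rate, "default": rate}).
    """
    doc = yaml.safe_load(open(path)) or {}
    out: dict = {}
    if "abcb" in doc:
        out["abcb_rules"] = {k: dict(v or {}) for k, v in doc["abcb"].items()}
    for key, name in (("pin", "pin_rules"), ("influx", "influx_rules")):
        if key in doc:
            out[name] = [
                (
                    r["cell_type"],
                    r.get("zone"),
                    r.get("face", "all"),
                    dict(r["members"]),
                )
                for r in doc[key]
            ]
    if "pd" in doc:
        pd: dict = {}
        for k, v in doc["pd"].items():
            pd[k if k == "default" else frozenset(k.split("|"))] = float(v)
        out["pd_rules"] = pd
    return out
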