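"""The two-level instrument hierarchy and its combination weights.

The instrument is organised as 5 domains -> 18 core characteristics ->
84 self-assessment items.  Each level carries *local* weights (summing
to 1 among siblings); a characteristic's *combination* (global) weight
is its local weight times its parent domain's local weight, so the 18
combination weights sum to 1.  The published weight table is shipped as
a packaged JSON fixture; because its weights are printed at two
decimals of a percent, the fixture is validated with a 0.1% slack on
the sum-to-one checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import InvalidInputError, SchemaError

__all__ = ["Domain", "Characteristic", "Hierarchy",
           "combination_weights", "load_hierarchy", "save_hierarchy"]

_STRICT_TOL = 1e-6


@dataclass(frozen=True)
class Domain:
    id: str
    name: str
    local_weight: float
    metadata: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class Characteristic:
    id: str
    name: str
    parent_domain: str
    local_weight: float
    n_items: int


@dataclass
class Hierarchy:
    """5-domain / 18-characteristic weighting tree.

    ``combination_weights`` maps characteristic id to its global weight;
    call :func:`combination_weights` to (re)derive them from the local
    weights.  ``weight_tolerance`` is the slack applied to the
    sum-to-one invariants (loosened to 1e-3 for fixtures built from
    printed, rounded weights).
    """

    domains: list[Domain]
    characteristics: list[Characteristic]
    combination_weights: dict[str, float] = field(default_factory=dict)
    weight_tolerance: float = _STRICT_TOL
    name: str = "hierarchy"

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------

    def domain(self, domain_id: str) -> Domain:
        for d in self.domains:
            if d.id == domain_id:
                return d
        raise InvalidInputError(f"unknown domain {domain_id!r}")

    def children(self, domain_id: str) -> list[Characteristic]:
        return [c for c in self.characteristics if c.parent_domain == domain_id]

    def characteristic(self, char_id: str) -> Characteristic:
        for c in self.characteristics:
            if c.id == char_id:
                return c
        raise InvalidInputError(f"unknown characteristic {char_id!r}")

    def characteristic_of_item(self, item_id: str) -> Characteristic:
        """Resolve canonical item ids of the form ``<char_id>.<k>``."""
        parent = str(item_id).rsplit(".", 1)[0]
        return self.characteristic(parent)

    def item_ids(self) -> list[str]:
        """Canonical item identifiers: ``<characteristic id>.<ordinal>``."""
        out: list[str] = []
        for c in self.characteristics:
            out.extend(f"{c.id}.{k}" for k in range(1, c.n_items + 1))
        return out

    @property
    def n_items(self) -> int:
        return sum(c.n_items for c in self.characteristics)

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        tol = self.weight_tolerance
        ids = [d.id for d in self.domains] + [c.id for c in self.characteristics]
        if len(set(ids)) != len(ids):
            raise SchemaError("domain/characteristic ids must be unique")
        dsum = sum(d.local_weight for d in self.domains)
        if abs(dsum - 1.0) > tol:
            raise SchemaError(f"domain weights sum to {dsum:.6f}, not 1 (tol {tol})")
        for d in self.domains:
            kids = self.children(d.id)
            if not kids:
                raise SchemaError(f"domain {d.id} has no characteristics")
            csum = sum(c.local_weight for c in kids)
            if abs(csum - 1.0) > tol:
                raise SchemaError(
                    f"characteristic weights in domain {d.id} sum to {csum:.6f}, not 1")
        orphans = {c.parent_domain for c in self.characteristics} - {d.id for d in self.domains}
        if orphans:
            raise SchemaError(f"characteristics reference unknown domains {orphans}")
        if self.combination_weights:
            total = sum(self.combination_weights.values())
            if abs(total - 1.0) > tol:
                raise SchemaError(
                    f"combination weights sum to {total:.6f}, not 1 (tol {tol})")


def combination_weights(h: Hierarchy) -> Hierarchy:
    """Fill in global weights: ``w(c) = local(c) * local(parent(c))``."""
    combo: dict[str, float] = {}
    for c in h.characteristics:
        d = h.domain(c.parent_domain)
        combo[c.id] = c.local_weight * d.local_weight
    h.combination_weights = combo
    h.validate()
    return h


def per_item_weights(h: Hierarchy) -> dict[str, float]:
    """Optional item-level weights: combination weight split evenly
    across a characteristic's items."""
    if not h.combination_weights:
        combination_weights(h)
    out: dict[str, float] = {}
    for c in h.characteristics:
        w = h.combination_weights[c.id] / c.n_items
        for k in range(1, c.n_items + 1):
            out[f"{c.id}.{k}"] = w
    return out


# -- serialisation -----------------------------------------------------

def _packaged_fixture():
    return resources.files("pmssa") / "data" / "hierarchy.json"


def load_hierarchy(path: str | Path | None = None) -> Hierarchy:
    """Load a hierarchy JSON; defaults to the packaged published table.

    Accepts either explicit ``local_weight`` per node or, for fixtures
    transcribed from printed tables, ``combination_weight_pct`` per
    characteristic, from which local weights are recovered (domain
    weight = sum of its children's global weights; characteristic local
    weight = its share within the domain).
    """
    src = _packaged_fixture() if path is None else Path(path)
    try:
        payload = json.loads(src.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed hierarchy JSON: {exc}") from exc
    tol = float(payload.get("weight_sum_tolerance", _STRICT_TOL))

    domains: list[Domain] = []
    chars: list[Characteristic] = []
    combo: dict[str, float] = {}
    for dom in payload.get("domains", []):
        kids = dom.get("characteristics", [])
        if not kids:
            raise SchemaError(f"domain {dom.get('id')!r} has no characteristics")
        if (all("combination_weight_pct" in c for c in kids)
                and not any("local_weight" in c for c in kids)):
            dom_total = sum(float(c["combination_weight_pct"]) for c in kids) / 100.0
            d_local = float(dom.get("local_weight", dom_total))
            locals_ = [float(c["combination_weight_pct"]) / 100.0 / dom_total for c in kids]
        else:
            try:
                d_local = float(dom["local_weight"])
                locals_ = [float(c["local_weight"]) for c in kids]
            except KeyError as exc:
                raise SchemaError(f"domain {dom.get('id')!r}: missing weight {exc}") from exc
        meta = {k: dom[k] for k in ("lambda_max", "cr") if k in dom}
        domains.append(Domain(id=str(dom["id"]), name=str(dom.get("name", dom["id"])),
                              local_weight=d_local, metadata=meta))
        for c, lw in zip(kids, locals_):
            chars.append(Characteristic(id=str(c["id"]),
                                        name=str(c.get("name", c["id"])),
                                        parent_domain=str(dom["id"]),
                                        local_weight=lw,
                                        n_items=int(c["n_items"])))
            if "combination_weight_pct" in c:
                combo[str(c["id"])] = float(c["combination_weight_pct"]) / 100.0

    h = Hierarchy(domains=domains, characteristics=chars,
                  combination_weights=combo, weight_tolerance=tol,
                  name=str(payload.get("name", src.stem)))
    if not combo:
        combination_weights(h)
    return h


def save_hierarchy(h: Hierarchy, path: str | Path) -> None:
    """Write a hierarchy as JSON (explicit local weights; round-trips
    exactly through :func:`load_hierarchy`)."""
    payload = {
        "name": h.name,
        "weight_sum_tolerance": h.weight_tolerance,
        "domains": [
            {
                "id": d.id, "name": d.name, "local_weight": d.local_weight,
                **d.metadata,
                "characteristics": [
                    {"id": c.id, "name": c.name, "local_weight": c.local_weight,
                     "n_items": c.n_items,
                     **({"combination_weight_pct": h.combination_weights[c.id] * 100.0}
                        if c.id in h.combination_weights else {})}
                    for c in h.children(d.id)
                ],
            }
            for d in h.domains
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
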