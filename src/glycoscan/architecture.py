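"""Domain architectures and protein classification.

Overlapping per-domain hits on one protein are resolved greedily by score
into an ordered, non-overlapping architecture, which is then classified:

* **SDGH** — single-domain glycoside hydrolase: exactly one domain, and it
  is a catalytic GH.
* **MDGH** — multi-domain GH: two or more domains, at least one catalytic
  GH (typically GH + carbohydrate-binding modules or other accessory
  domains).
* **MAGH** — multi-activity GH: an MDGH carrying at least two catalytic
  domains (GH or carbohydrate esterase), including same-family repeats
  (multi-GHx).
* **non_GH** — everything else.

For MAGHs, each pair of catalytic domains is typed by its potential mode
of synergy: parallel-pathway (PPS, distinct substrates, both backbone
hydrolases, e.g. cellulase:xylanase), debranching (DS, same substrate,
exactly one side-group-cleaving domain, e.g. xylanase:esterase), or
linear-pathway (LPS, same substrate, backbone hydrolase feeding an
oligosaccharidase).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .errors import InputError
from .scan import DomainHit

ROLES = frozenset({"catalytic_GH", "catalytic_CE", "accessory"})
SUBSTRATES = frozenset({"cellulose", "xylan", "chitin", "other", "none"})
ACTIONS = frozenset(
    {"backbone_hydrolase", "debrancher", "oligosaccharidase", "binding", "other"}
)
CLASS_LABELS = ("SDGH", "MDGH", "MAGH", "non_GH")
SYNERGY_TYPES = ("LPS", "PPS", "DS", "none")

CATALOG_COLUMNS = ["accession", "family", "role", "substrate", "action"]


@dataclass(frozen=True)
class FamilyEntry:
    accession: str
    family: str
    role: str
    substrate: str
    action: str


class FamilyCatalog:
    """Maps profile accessions to family name, role, substrate and action.

    A bundled default covers the cellulase / xylanase / chitinase GH
    families, carbohydrate-esterase entries, and the common accessory
    domains (CBMs, dockerins, fibronectin-III modules, ...).
    """

    def __init__(self, entries: list[FamilyEntry]):
        seen: dict[str, FamilyEntry] = {}
        for e in entries:
            if e.accession in seen:
                raise InputError(f"duplicate catalog accession {e.accession}")
            if e.role not in ROLES:
                raise InputError(f"{e.accession}: unknown role {e.role!r}")
            if e.substrate not in SUBSTRATES:
                raise InputError(f"{e.accession}: unknown substrate {e.substrate!r}")
            if e.action not in ACTIONS:
                raise InputError(f"{e.accession}: unknown action {e.action!r}")
            if e.role != "accessory" and e.substrate == "none":
                raise InputError(
                    f"{e.accession}: catalytic entry must name a substrate"
                )
            seen[e.accession] = e
        self._by_accession = seen
        self._by_family: dict[str, FamilyEntry] = {}
        for e in entries:
            self._by_family.setdefault(e.family, e)

    def __len__(self) -> int:
        return len(self._by_accession)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def get(self, accession: str) -> FamilyEntry | None:
        return self._by_accession.get(accession)

    def by_family(self, family: str) -> FamilyEntry | None:
        return self._by_family.get(family)

    @property
    def entries(self) -> list[FamilyEntry]:
        return list(self._by_accession.values())

    def accessions_for_role(self, *roles: str) -> set[str]:
        return {a for a, e in self._by_accession.items() if e.role in roles}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FamilyCatalog":
        missing = set(CATALOG_COLUMNS) - set(df.columns)
        if missing:
            raise InputError(f"catalog missing columns: {sorted(missing)}")
        return cls(
            [FamilyEntry(*[str(r[c]) for c in CATALOG_COLUMNS]) for _, r in df.iterrows()]
        )

    @classmethod
    def from_tsv(cls, path) -> "FamilyCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [[getattr(e, c) for c in CATALOG_COLUMNS] for e in self.entries],
            columns=CATALOG_COLUMNS,
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def default(cls) -> "FamilyCatalog":
        ref = importlib.resources.files("glycoscan.data") / "default_catalog.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass
class ProteinArchitecture:
    """The resolved, ordered domain content of one protein."""

    protein_id: str
    domains: list[DomainHit]
    arch_string: str
    class_label: str
    repeat_families: dict[str, int] = field(default_factory=dict)
    synergy_calls: list[tuple[tuple[str, str], str]] = field(default_factory=list)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def families(self) -> list[str]:
        return [d.family for d in self.domains]

    @property
    def is_mdgh(self) -> bool:
        """MAGH is a sub-class of MDGH."""
        return self.class_label in ("MDGH", "MAGH")


def resolve_overlaps(
    hits: list[DomainHit], tolerance_fraction: float = 0.5
) -> list[DomainHit]:
    """Greedy score-ordered selection of mutually compatible hits.

    Hits are taken in order of descending bit score (ties: lower E-value,
    lower start, lexicographic accession); a hit is kept iff its overlap
    with every already-kept hit is at most ``tolerance_fraction`` of the
    shorter of the two.  Output is sorted by start coordinate.
    """
    if not 0 <= tolerance_fraction < 1:
        raise InputError("tolerance_fraction must be in [0, 1)")
    if not hits:
        return []
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise InputError(
            f"resolve_overlaps got hits from multiple proteins: {sorted(proteins)}"
        )
    ordered = sorted(
        hits, key=lambda h: (-h.bit_score, h.evalue, h.ali_start, h.accession)
    )
    kept: list[DomainHit] = []
    for h in ordered:
        ok = True
        for k in kept:
            ov = min(h.ali_end, k.ali_end) - max(h.ali_start, k.ali_start) + 1
            if ov > tolerance_fraction * min(h.length, k.length):
                ok = False
                break
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: h.ali_start)
    return kept


def _roles(domains: list[DomainHit], catalog: FamilyCatalog, warn: list[str] | None):
    roles = []
    for d in domains:
        entry = catalog.get(d.accession)
        if entry is None:
            entry = catalog.by_family(d.family)
        if entry is None:
            if warn is not None:
                warn.append(
                    f"{d.protein_id}: accession {d.accession} ({d.family}) "
                    f"not in catalog; treated as accessory"
                )
            roles.append("accessory")
        else:
            roles.append(entry.role)
    return roles


def classify(
    domains: list[DomainHit],
    catalog: FamilyCatalog,
    warnings: list[str] | None = None,
) -> tuple[str, dict[str, int]]:
    """Class label and repeated families for an overlap-resolved domain list.

    Unknown accessions degrade to role ``accessory`` and are reported on
    the warnings channel, never dropped.
    """
    roles = _roles(domains, catalog, warnings)
    n = len(domains)
    n_gh = sum(r == "catalytic_GH" for r in roles)
    n_cat = sum(r in ("catalytic_GH", "catalytic_CE") for r in roles)
    if n == 1 and n_gh == 1:
        label = "SDGH"
    elif n >= 2 and n_gh >= 1:
        label = "MAGH" if n_cat >= 2 else "MDGH"
    else:
        label = "non_GH"
    counts: dict[str, int] = {}
    for d in domains:
        counts[d.family] = counts.get(d.family, 0) + 1
    repeats = {f: c for f, c in counts.items() if c >= 2}
    return label, repeats


def classify_synergy(
    domains: list[DomainHit], catalog: FamilyCatalog
) -> list[tuple[tuple[str, str], str]]:
    """Synergy type of each unordered pair of catalytic families.

    Requires a multi-activity input (>= 2 catalytic domains).  Same-family
    repeat pairs are typed ``none``.
    """
    cat_entries = []
    for d in domains:
        entry = catalog.get(d.accession) or catalog.by_family(d.family)
        if entry is not None and entry.role in ("catalytic_GH", "catalytic_CE"):
            cat_entries.append(entry)
    if len(cat_entries) < 2:
        raise InputError("classify_synergy requires >= 2 catalytic domains")

    pairs: dict[tuple[str, str], tuple[FamilyEntry, FamilyEntry]] = {}
    for a, b in combinations(cat_entries, 2):
        key = tuple(sorted((a.family, b.family)))
        pairs.setdefault(key, (a, b))

    calls = []
    for key in sorted(pairs):
        a, b = pairs[key]
        calls.append((key, _synergy_type(a, b)))
    return calls


def _synergy_type(a: FamilyEntry, b: FamilyEntry) -> str:
    if a.family == b.family:
        return "none"
    if a.substrate != b.substrate:
        if a.action == b.action == "backbone_hydrolase":
            return "PPS"
        return "none"
    # same substrate
    if (a.action == "debrancher") != (b.action == "debrancher"):
        return "DS"
    actions = {a.action, b.action}
    if actions == {"backbone_hydrolase", "oligosaccharidase"}:
        return "LPS"
    return "none"


def build_architectures(
    hits: list[DomainHit],
    catalog: FamilyCatalog,
    tolerance_fraction: float = 0.5,
    warnings: list[str] | None = None,
) -> list[ProteinArchitecture]:
    """Group hits per protein, resolve overlaps, classify, type synergy.

    Output is ordered by protein id and invariant to the input hit order.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    archs = []
    for pid in sorted(by_protein):
        resolved = resolve_overlaps(by_protein[pid], tolerance_fraction)
        label, repeats = classify(resolved, catalog, warnings)
        synergy: list[tuple[tuple[str, str], str]] = []
        if label == "MAGH":
            synergy = classify_synergy(resolved, catalog)
        archs.append(
            ProteinArchitecture(
                protein_id=pid,
                domains=resolved,
                arch_string="-".join(d.family for d in resolved),
                class_label=label,
                repeat_families=repeats,
                synergy_calls=synergy,
            )
        )
    return archs


# ---------------------------------------------------------------------------
# Architecture table I/O
# ---------------------------------------------------------------------------

ARCH_COLUMNS = [
    "protein_id",
    "class_label",
    "arch_string",
    "n_domains",
    "n_catalytic",
    "repeat_families",
    "synergy_calls",
]


def architectures_to_frame(
    archs: list[ProteinArchitecture], catalog: FamilyCatalog
) -> pd.DataFrame:
    rows = []
    for a in archs:
        roles = _roles(a.domains, catalog, None)
        n_cat = sum(r in ("catalytic_GH", "catalytic_CE") for r in roles)
        repeats = ";".join(f"{f}x{c}" for f, c in sorted(a.repeat_families.items()))
        synergy = ";".join(f"{p[0]}:{p[1]}={t}" for p, t in a.synergy_calls)
        rows.append(
            [a.protein_id, a.class_label, a.arch_string, a.n_domains, n_cat, repeats, synergy]
        )
    return pd.DataFrame(rows, columns=ARCH_COLUMNS)


def write_architecture_table(
    archs: list[ProteinArchitecture], catalog: FamilyCatalog, path
) -> None:
    architectures_to_frame(archs, catalog).to_csv(path, sep="\t", index=False)
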