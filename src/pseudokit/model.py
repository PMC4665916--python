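"""Data-layer model of reversible pseudonymization.

Pseudonymization here means separating each subject's *identifying* (master)
attributes from its *payload* (clinical/document) attributes into distinct
pools, linked only through arbitrary codes (pseudonyms):

* **one-tier**: both pools are keyed by the *same* pseudonym per record, so
  holding both pools suffices to join them;
* **two-tier**: each pool lives in its own namespace with its own pseudonyms,
  and a separate mapping table of pseudonym pairs is the sole link between
  them.  Deleting the mapping table makes the pools unjoinable.

``integrate`` reverses either separation (de-pseudonymization), reporting —
never silently dropping — entries that cannot be linked.

Attribute categories are always declared explicitly by the dataset schema.
Which attributes of a real dataset are identifying is a governance decision
this module refuses to guess.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

IDENTIFYING = "identifying"
PAYLOAD = "payload"
CATEGORIES = (IDENTIFYING, PAYLOAD)

# 128-bit random pseudonyms, rendered as 32 lowercase hex characters.
PSEUDONYM_BITS = 128


class ModelError(ValueError):
    """Base class for data-model violations."""


class DuplicateSubjectKeyError(ModelError):
    pass


class CategoryError(ModelError):
    """An attribute carries no category or an unknown one."""


class NamespaceError(ModelError):
    """Namespace constraints violated (e.g. two-tier with a single namespace)."""


@dataclass(frozen=True)
class AttributeValue:
    """A single named value with its declared category."""

    name: str
    value: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CategoryError(
                f"attribute {self.name!r}: undeclared category {self.category!r}"
            )


@dataclass(frozen=True)
class Namespace:
    """Label of the component owning a set of identifiers."""

    id: str


@dataclass(frozen=True)
class Pseudonym:
    """An arbitrary code standing in for a subject within one namespace."""

    namespace: Namespace
    value: str


@dataclass(frozen=True)
class IntegratedRecord:
    """One subject's logical global record: all attributes, both categories."""

    subject_key: str
    attributes: tuple[AttributeValue, ...]

    def by_category(self, category: str) -> dict[str, str]:
        return {a.name: a.value for a in self.attributes if a.category == category}

    @property
    def identifying(self) -> dict[str, str]:
        return self.by_category(IDENTIFYING)

    @property
    def payload(self) -> dict[str, str]:
        return self.by_category(PAYLOAD)

    def attribute_dict(self) -> dict[str, tuple[str, str]]:
        """name -> (value, category), the order-insensitive view of the record."""
        return {a.name: (a.value, a.category) for a in self.attributes}


@dataclass
class IntegratedDataset:
    """A collection of integrated records with unique subject keys."""

    records: list[IntegratedRecord] = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.subject_key in seen:
                raise DuplicateSubjectKeyError(
                    f"duplicate subject_key {rec.subject_key!r}"
                )
            seen.add(rec.subject_key)
            if not self.degenerate:
                cats = {a.category for a in rec.attributes}
                if cats != {IDENTIFYING, PAYLOAD}:
                    raise CategoryError(
                        f"record {rec.subject_key!r} needs at least one identifying "
                        "and one payload attribute (or declare the dataset degenerate)"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IntegratedRecord]:
        return iter(self.records)

    def content_multiset(self) -> list[tuple[tuple[str, tuple[str, str]], ...]]:
        """Sorted multiset of record contents, ignoring subject keys and order.

        Two datasets describe the same subjects iff their multisets compare
        equal; this is the package-wide notion of record equality.
        """
        return sorted(
            tuple(sorted(rec.attribute_dict().items())) for rec in self.records
        )


def datasets_equivalent(a: IntegratedDataset, b: IntegratedDataset) -> bool:
    """Order- and subject-key-insensitive equality of two datasets."""
    return a.content_multiset() == b.content_multiset()


@dataclass
class Pool:
    """Pseudonym-keyed store of attributes of exactly one category."""

    namespace: Namespace
    category: str
    entries: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CategoryError(f"pool category {self.category!r} unknown")

    def add(self, pseudonym: Pseudonym, attrs: Mapping[str, str]) -> None:
        if pseudonym.namespace != self.namespace:
            raise NamespaceError(
                f"pseudonym namespace {pseudonym.namespace.id!r} does not match "
                f"pool namespace {self.namespace.id!r}"
            )
        self.entries[pseudonym.value] = dict(attrs)

    def __len__(self) -> int:
        return len(self.entries)

    def pseudonym_values(self) -> set[str]:
        return set(self.entries)

    def to_jsonl(self) -> str:
        lines = []
        for value in sorted(self.entries):
            lines.append(
                json.dumps(
                    {
                        "namespace": self.namespace.id,
                        "pseudonym": value,
                        "attributes": self.entries[value],
                    },
                    sort_keys=True,
                )
            )
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_jsonl(cls, text: str, category: str) -> "Pool":
        entries: dict[str, dict[str, str]] = {}
        namespace: Namespace | None = None
        for line in text.splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            ns = Namespace(obj["namespace"])
            if namespace is None:
                namespace = ns
            elif ns != namespace:
                raise NamespaceError("mixed namespaces in pool serialization")
            entries[obj["pseudonym"]] = dict(obj["attributes"])
        if namespace is None:
            raise ModelError("cannot infer namespace from empty pool serialization")
        pool = cls(namespace=namespace, category=category)
        pool.entries = entries
        return pool


@dataclass
class MappingTable:
    """Bare pseudonym pairs linking two namespaces; holds no attribute values."""

    pairs: list[tuple[Pseudonym, Pseudonym]] = field(default_factory=list)

    def add(self, a: Pseudonym, b: Pseudonym) -> None:
        if a.namespace == b.namespace:
            raise NamespaceError("a mapping pair must span two distinct namespaces")
        for pa, pb in self.pairs:
            if pa.value == a.value or pb.value == b.value:
                raise ModelError("pseudonym already mapped; pairs must be unique")
        self.pairs.append((a, b))

    def lookup_a(self, value_a: str) -> Pseudonym | None:
        for pa, pb in self.pairs:
            if pa.value == value_a:
                return pb
        return None

    def lookup_b(self, value_b: str) -> Pseudonym | None:
        for pa, pb in self.pairs:
            if pb.value == value_b:
                return pa
        return None

    def __len__(self) -> int:
        return len(self.pairs)

    def to_jsonl(self) -> str:
        lines = []
        for pa, pb in self.pairs:
            lines.append(
                json.dumps(
                    {
                        "pseudonym_a": {"namespace": pa.namespace.id, "value": pa.value},
                        "pseudonym_b": {"namespace": pb.namespace.id, "value": pb.value},
                    },
                    sort_keys=True,
                )
            )
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_jsonl(cls, text: str) -> "MappingTable":
        table = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            table.add(
                Pseudonym(Namespace(obj["pseudonym_a"]["namespace"]), obj["pseudonym_a"]["value"]),
                Pseudonym(Namespace(obj["pseudonym_b"]["namespace"]), obj["pseudonym_b"]["value"]),
            )
        return table


def new_pseudonym(ns: Namespace, rng: random.Random, taken: set[str] | None = None) -> Pseudonym:
    """Draw a fresh 128-bit random pseudonym, independent of any subject content."""
    while True:
        value = format(rng.getrandbits(PSEUDONYM_BITS), "032x")
        if taken is None or value not in taken:
            if taken is not None:
                taken.add(value)
            return Pseudonym(ns, value)


def pseudonymize_one_tier(
    dataset: IntegratedDataset, ns: Namespace, rng_seed: int
) -> tuple[Pool, Pool]:
    """Separate a dataset into master and payload pools sharing one pseudonym."""
    rng = random.Random(rng_seed)
    master = Pool(ns, IDENTIFYING)
    payload = Pool(ns, PAYLOAD)
    taken: set[str] = set()
    for rec in dataset:
        p = new_pseudonym(ns, rng, taken)
        master.add(p, rec.identifying)
        payload.add(p, rec.payload)
    return master, payload


def pseudonymize_two_tier(
    dataset: IntegratedDataset, ns_a: Namespace, ns_b: Namespace, rng_seed: int
) -> tuple[Pool, Pool, MappingTable]:
    """Separate a dataset into pools with disjoint namespaces plus a mapping table.

    The mapping table is the unique artifact linking the two pools; each
    record yields exactly one pair (cascading identifiers).
    """
    if ns_a == ns_b:
        raise NamespaceError("two-tier separation requires two distinct namespaces")
    rng = random.Random(rng_seed)
    master = Pool(ns_a, IDENTIFYING)
    payload = Pool(ns_b, PAYLOAD)
    mapping = MappingTable()
    taken: set[str] = set()  # shared so the two pools' value sets stay disjoint
    for rec in dataset:
        pa = new_pseudonym(ns_a, rng, taken)
        pb = new_pseudonym(ns_b, rng, taken)
        master.add(pa, rec.identifying)
        payload.add(pb, rec.payload)
        mapping.add(pa, pb)
    return master, payload, mapping


@dataclass(frozen=True)
class UnmatchedEntry:
    """A pool entry or mapping pair that could not be joined."""

    namespace: str
    pseudonym: str
    reason: str  # "no-pair", "dangling-link"


@dataclass
class IntegrationResult:
    """Outcome of de-pseudonymization: joined records plus a side report."""

    dataset: IntegratedDataset
    unmatched: list[UnmatchedEntry] = field(default_factory=list)


def _record_from(
    key: str, master_attrs: Mapping[str, str], payload_attrs: Mapping[str, str]
) -> IntegratedRecord:
    attrs = tuple(
        [AttributeValue(n, v, IDENTIFYING) for n, v in sorted(master_attrs.items())]
        + [AttributeValue(n, v, PAYLOAD) for n, v in sorted(payload_attrs.items())]
    )
    return IntegratedRecord(subject_key=key, attributes=attrs)


def integrate(
    master_pool: Pool,
    payload_pool: Pool,
    mapping: MappingTable | None = None,
) -> IntegrationResult:
    """Reconstruct the integrated dataset from separated pools.

    With ``mapping=None`` the pools must share a namespace (one-tier) and are
    joined on equal pseudonyms.  Otherwise the mapping table drives the join.
    Reconstructed records are keyed by the master-pool pseudonym (the source
    subject keys are, by design, unrecoverable).  Entries without a partner
    and pairs pointing at absent entries are reported, never dropped.
    """
    records: list[IntegratedRecord] = []
    unmatched: list[UnmatchedEntry] = []
    used_master: set[str] = set()
    used_payload: set[str] = set()

    if mapping is None:
        if master_pool.namespace != payload_pool.namespace:
            raise NamespaceError(
                "one-tier integration requires pools sharing a namespace; "
                "supply the mapping table for two-tier pools"
            )
        for value in sorted(master_pool.entries):
            if value in payload_pool.entries:
                records.append(
                    _record_from(value, master_pool.entries[value], payload_pool.entries[value])
                )
                used_master.add(value)
                used_payload.add(value)
    else:
        for pa, pb in mapping.pairs:
            a_present = pa.value in master_pool.entries
            b_present = pb.value in payload_pool.entries
            if a_present and b_present:
                records.append(
                    _record_from(
                        pa.value, master_pool.entries[pa.value], payload_pool.entries[pb.value]
                    )
                )
                used_master.add(pa.value)
                used_payload.add(pb.value)
            else:
                if not a_present:
                    unmatched.append(
                        UnmatchedEntry(pa.namespace.id, pa.value, "dangling-link")
                    )
                if not b_present:
                    unmatched.append(
                        UnmatchedEntry(pb.namespace.id, pb.value, "dangling-link")
                    )

    for value in sorted(master_pool.pseudonym_values() - used_master):
        unmatched.append(UnmatchedEntry(master_pool.namespace.id, value, "no-pair"))
    for value in sorted(payload_pool.pseudonym_values() - used_payload):
        unmatched.append(UnmatchedEntry(payload_pool.namespace.id, value, "no-pair"))

    dataset = IntegratedDataset(records=records, degenerate=True)
    return IntegrationResult(dataset=dataset, unmatched=unmatched)


# ---------------------------------------------------------------------------
# External interface: CSV dataset + key-value schema file
# ---------------------------------------------------------------------------

SUBJECT_KEY_FIELD = "subject_key"


def write_schema(path: str | Path, categories: Mapping[str, str], key_column: str) -> None:
    lines = [f"{SUBJECT_KEY_FIELD} = {key_column}"]
    for name in sorted(categories):
        lines.append(f"{name} = {categories[name]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_schema(path: str | Path) -> tuple[dict[str, str], str]:
    """Parse a key-value schema file; returns (column -> category, key column)."""
    categories: dict[str, str] = {}
    key_column: str | None = None
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ModelError(f"malformed schema line: {raw!r}")
        name, _, value = line.partition("=")
        name, value = name.strip(), value.strip()
        if name == SUBJECT_KEY_FIELD:
            key_column = value
        else:
            if value not in CATEGORIES:
                raise CategoryError(f"column {name!r}: undeclared category {value!r}")
            categories[name] = value
    if key_column is None:
        raise ModelError(f"schema file must declare '{SUBJECT_KEY_FIELD} = <column>'")
    return categories, key_column


def write_dataset_csv(
    dataset: IntegratedDataset, csv_path: str | Path, schema_path: str | Path
) -> None:
    columns: dict[str, str] = {}
    for rec in dataset:
        for a in rec.attributes:
            prev = columns.setdefault(a.name, a.category)
            if prev != a.category:
                raise CategoryError(f"column {a.name!r} declared with two categories")
    names = sorted(columns)
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([SUBJECT_KEY_FIELD] + names)
        for rec in dataset:
            row = rec.attribute_dict()
            writer.writerow([rec.subject_key] + [row.get(n, ("", ""))[0] for n in names])
    write_schema(schema_path, columns, SUBJECT_KEY_FIELD)


def read_dataset_csv(csv_path: str | Path, schema_path: str | Path) -> IntegratedDataset:
    categories, key_column = read_schema(schema_path)
    records: list[IntegratedRecord] = []
    with open(csv_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return IntegratedDataset(records=[], degenerate=True)
        for row in reader:
            key = row.pop(key_column)
            attrs = []
            for name, value in row.items():
                if name not in categories:
                    raise CategoryError(f"column {name!r} missing from schema")
                if value != "":
                    attrs.append(AttributeValue(name, value, categories[name]))
            records.append(IntegratedRecord(subject_key=key, attributes=tuple(attrs)))
    return IntegratedDataset(records=records)
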