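"""Deterministic synthetic registry generator.

Emulates the content of a multi-site rare-disease registry: per-subject
identifying master data (synthetic name, birth date, institution) and a set
of structured payload documents (eCRF instances) per subject, with subjects
distributed round-robin over sites.  All names are drawn from a bundled
synthetic word list; no real-person data is ever used.

The generator emits subject keys only — pseudonyms are created exclusively
by the separation operations in :mod:`pseudokit.model` — and is byte-
deterministic under its seed so every fixture in the test suite can be
re-generated instead of shipped.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .model import (
    IDENTIFYING,
    PAYLOAD,
    AttributeValue,
    IntegratedDataset,
    IntegratedRecord,
    write_dataset_csv,
)

# Synthetic name material (invented strings, not sampled from any real roster).
_FIRST_NAMES = [
    "Alba", "Boren", "Cathi", "Doran", "Elia", "Fenn", "Galia", "Hobe",
    "Imra", "Jost", "Kelda", "Loric", "Mave", "Nerin", "Odra", "Pellam",
    "Quin", "Rasa", "Soren", "Tilde", "Ulfin", "Vesna", "Wendel", "Xara",
    "Ysolt", "Zeno",
]
_LAST_NAMES = [
    "Ashgrove", "Birchall", "Cresting", "Dunmore", "Eastvale", "Fernsby",
    "Graymarsh", "Hollowell", "Ironwood", "Juniper", "Kestrel", "Larkmoor",
    "Millbrook", "Northgate", "Oakhurst", "Pinewick", "Quarry", "Redfern",
    "Stonefield", "Thornbury", "Underhill", "Vexford", "Westbrook", "Yarrow",
]

DEFAULT_DOC_TYPES: dict[str, tuple[str, ...]] = {
    "baseline_visit": ("diagnosis_code", "onset_age", "severity_score"),
    "followup_visit": ("visit_no", "symptom_score", "medication"),
    "specimen_registration": ("kit_id", "sample_type", "volume_ml"),
}

ROLES_PER_SITE = ("physician", "lab")


@dataclass(frozen=True)
class Document:
    doc_type: str
    content: dict[str, str]


@dataclass(frozen=True)
class Subject:
    subject_key: str
    site: str
    identifying: dict[str, str]
    documents: tuple[Document, ...]


@dataclass(frozen=True)
class UserSpec:
    username: str
    secret: str
    role: str
    site: str


@dataclass
class GeneratorSpec:
    """Parameters of a synthetic registry.

    Defaults model a small multi-site observational registry: 10 subjects
    across 3 sites with 2 payload documents per subject.
    """

    n_subjects: int = 10
    n_sites: int = 3
    docs_per_subject: tuple[int, int] = (2, 2)
    doc_types: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DOC_TYPES)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        lo, hi = self.docs_per_subject
        if lo < 0 or hi < lo:
            raise ValueError("docs_per_subject must be a non-empty range")
        if not self.doc_types:
            raise ValueError("at least one document type is required")


@dataclass
class Registry:
    """A generated integrated registry plus its user directory."""

    subjects: list[Subject]
    users: list[UserSpec]
    sites: list[str]
    spec: GeneratorSpec

    def to_dataset(self) -> IntegratedDataset:
        """Flatten subjects into an integrated dataset.

        Document fields become payload attributes named
        ``<doc_type>#<ordinal>.<field>`` so that distinct document
        instances never collide.
        """
        records = []
        for s in self.subjects:
            attrs: list[AttributeValue] = [
                AttributeValue(name, value, IDENTIFYING)
                for name, value in sorted(s.identifying.items())
            ]
            counters: dict[str, int] = {}
            for doc in s.documents:
                ordinal = counters.get(doc.doc_type, 0)
                counters[doc.doc_type] = ordinal + 1
                for fname, fval in sorted(doc.content.items()):
                    attrs.append(
                        AttributeValue(f"{doc.doc_type}#{ordinal}.{fname}", fval, PAYLOAD)
                    )
            records.append(
                IntegratedRecord(subject_key=s.subject_key, attributes=tuple(attrs))
            )
        return IntegratedDataset(records=records, degenerate=not records)

    def write_csv(self, csv_path: str | Path, schema_path: str | Path) -> None:
        write_dataset_csv(self.to_dataset(), csv_path, schema_path)


def _field_value(field_name: str, rng: random.Random) -> str:
    if field_name.endswith("_code"):
        return f"G{rng.randrange(10, 99)}.{rng.randrange(0, 9)}"
    if field_name.endswith(("_age", "_no")):
        return str(rng.randrange(0, 80))
    if field_name.endswith("_score"):
        return str(rng.randrange(0, 100))
    if field_name.endswith("_id"):
        return f"KIT-{rng.randrange(10000, 99999)}"
    if field_name.endswith("_ml"):
        return f"{rng.randrange(1, 50) / 10:.1f}"
    if field_name == "sample_type":
        return rng.choice(["blood", "serum", "fibroblast", "urine"])
    if field_name == "medication":
        return rng.choice(["none", "coq10", "riboflavin", "carnitine"])
    return f"v{rng.randrange(0, 1000)}"


def generate_registry(spec: GeneratorSpec) -> Registry:
    """Generate a registry deterministically from the spec and its seed."""
    spec.validate()
    rng = random.Random(spec.seed)
    sites = [f"site-{i + 1:02d}" for i in range(spec.n_sites)]
    doc_type_names = sorted(spec.doc_types)

    subjects: list[Subject] = []
    for i in range(spec.n_subjects):
        site = sites[i % spec.n_sites]  # round-robin site assignment
        first = rng.choice(_FIRST_NAMES)
        last = rng.choice(_LAST_NAMES)
        birth = (
            f"{rng.randrange(1930, 2015)}-{rng.randrange(1, 13):02d}-"
            f"{rng.randrange(1, 29):02d}"
        )
        identifying = {
            "name": f"{first} {last}",
            "birth_date": birth,
            "institution": site,
        }
        lo, hi = spec.docs_per_subject
        n_docs = rng.randint(lo, hi)
        docs = []
        for _ in range(n_docs):
            doc_type = rng.choice(doc_type_names)
            content = {
                fname: _field_value(fname, rng) for fname in spec.doc_types[doc_type]
            }
            docs.append(Document(doc_type=doc_type, content=content))
        subjects.append(
            Subject(
                subject_key=f"subj-{i + 1:04d}",
                site=site,
                identifying=identifying,
                documents=tuple(docs),
            )
        )

    users = [
        UserSpec("admin", f"adm-{rng.getrandbits(48):012x}", "administrator", sites[0]),
        UserSpec("monitor1", f"mon-{rng.getrandbits(48):012x}", "monitor", sites[0]),
    ]
    for site in sites:
        for role in ROLES_PER_SITE:
            users.append(
                UserSpec(
                    f"{role[:4]}_{site}", f"{role[:3]}-{rng.getrandbits(48):012x}",
                    role, site,
                )
            )
    return Registry(subjects=subjects, users=users, sites=sites, spec=spec)


def example_three_subjects() -> IntegratedDataset:
    """The canonical three-record worked example.

    Two attributes per record: ``Attr1`` (identifying) with values A, B, C
    and ``Attr2`` (payload) with values D, E, F, paired in order A–D, B–E,
    C–F.  This is the smallest dataset exhibiting separation, and the
    running example for one-tier vs two-tier pseudonymization.
    """
    records = []
    for ident, pay in (("A", "D"), ("B", "E"), ("C", "F")):
        records.append(
            IntegratedRecord(
                subject_key=f"entry-{ident}",
                attributes=(
                    AttributeValue("Attr1", ident, IDENTIFYING),
                    AttributeValue("Attr2", pay, PAYLOAD),
                ),
            )
        )
    return IntegratedDataset(records=records)
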