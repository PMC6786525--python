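"""MeSH vocabulary handling and category classification.

MeSH (Medical Subject Headings) descriptors live at one or more *tree
addresses* — dot-separated paths such as ``B01.050`` — in a hierarchy whose
top-level branches group anatomy (A), organisms (B), diseases (C), chemicals
and drugs (D), techniques and equipment (E), and so on.  A fixed set of
address rules places an article in up to six content categories:

* ``HUMAN``    — the Humans descriptor or anything under M01 (Persons);
* ``ANIMAL``   — anything under B01 (Eukaryota) except the Humans address;
* ``MOLCELL``  — cells (A11), archaea/bacteria/viruses (B02–B04), molecular
  structure (G02.111.570) or chemical processes (G02.149);
* ``DISEASE``  — the C branch except C22 (animal diseases);
* ``THERAP``   — the E branch (therapeutic/diagnostic approaches) except E07
  (equipment and supplies);
* ``CHEMDRUG`` — the D branch (chemicals and drugs).

The first three (``HAMC``) position an article in the triangle of
biomedicine; the last three become the binary D/E/CD modifier flags of its
data profile.
"""

from __future__ import annotations

import json
import logging
import re
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

logger = logging.getLogger("aptcite")

__all__ = [
    "Category",
    "HAMC_CATEGORIES",
    "MODIFIER_CATEGORIES",
    "TreeAddress",
    "MeshVocabulary",
    "ArticleRecord",
    "UnknownDescriptorError",
    "classify_address",
    "classify_term",
    "category_counts",
    "is_clinical_article",
    "CLINICAL_PUB_TYPES",
    "read_articles_jsonl",
    "write_articles_jsonl",
]


class Category(Enum):
    """The six MeSH-derived content categories."""

    HUMAN = "HUMAN"
    ANIMAL = "ANIMAL"
    MOLCELL = "MOLCELL"
    DISEASE = "DISEASE"
    THERAP = "THERAP"
    CHEMDRUG = "CHEMDRUG"


#: the triangle-of-biomedicine subset
HAMC_CATEGORIES = (Category.HUMAN, Category.ANIMAL, Category.MOLCELL)
#: the binary modifier-flag subset (D, E, CD)
MODIFIER_CATEGORIES = (Category.DISEASE, Category.THERAP, Category.CHEMDRUG)

#: The single tree address of the Humans descriptor.
HUMANS_ADDRESS = "B01.050.150.900.649.801.400.112.400.400"

#: Tree prefixes whose descendants count as Molecular/Cellular Biology:
#: cells, archaea, bacteria, viruses, molecular structure, chemical processes.
MOLCELL_ROOTS = ("A11", "B02", "B03", "B04", "G02.111.570", "G02.149")

_SEGMENT_RE = re.compile(r"^[A-Z][0-9]+$")


class AddressError(ValueError):
    """Raised for a malformed MeSH tree address."""


class UnknownDescriptorError(KeyError):
    """Raised in strict mode when a descriptor is absent from the vocabulary."""


@dataclass(frozen=True, order=True)
class TreeAddress:
    """A dot-separated position in the MeSH tree, e.g. ``B01.050``.

    The descendant relation is the segment-prefix relation:
    ``B01.050.150`` descends from ``B01.050`` and from ``B01``, but
    ``B010`` does not descend from ``B01``.
    """

    address: str

    def __post_init__(self) -> None:
        segments = self.address.split(".")
        if not segments or not all(_SEGMENT_RE.match(s) or (i > 0 and s.isdigit())
                                   for i, s in enumerate(segments)):
            raise AddressError(f"malformed MeSH tree address: {self.address!r}")

    @property
    def branch(self) -> str:
        """The top-level letter of the tree branch (``C`` for ``C04.557``)."""
        return self.address[0]

    def is_or_descends_from(self, other: "TreeAddress | str") -> bool:
        prefix = other.address if isinstance(other, TreeAddress) else other
        return self.address == prefix or self.address.startswith(prefix + ".")

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.address


def classify_address(address: TreeAddress | str) -> set[Category]:
    """Classify a single tree address into the categories it triggers.

    Pure function; the returned set may be empty (e.g. for Z-branch
    geographic addresses) and may hold several categories, though never
    HUMAN and ANIMAL together: the Humans address is carved out of B01.
    """
    if isinstance(address, str):
        address = TreeAddress(address)
    cats: set[Category] = set()
    if address.address == HUMANS_ADDRESS or address.is_or_descends_from("M01"):
        cats.add(Category.HUMAN)
    if address.is_or_descends_from("B01") and address.address != HUMANS_ADDRESS:
        cats.add(Category.ANIMAL)
    if any(address.is_or_descends_from(root) for root in MOLCELL_ROOTS):
        cats.add(Category.MOLCELL)
    if address.branch == "C" and not address.is_or_descends_from("C22"):
        cats.add(Category.DISEASE)
    if address.branch == "E" and not address.is_or_descends_from("E07"):
        cats.add(Category.THERAP)
    if address.branch == "D":
        cats.add(Category.CHEMDRUG)
    return cats


@dataclass
class MeshVocabulary:
    """Maps each descriptor name to its set of tree addresses.

    ``strict`` controls unknown-descriptor handling: by default a lookup of
    a descriptor absent from the vocabulary raises
    :class:`UnknownDescriptorError`; in lenient mode it logs a warning and
    yields no addresses (so the term simply classifies into no category).
    Qualifier strings attached with a slash (``Neoplasms/drug therapy``)
    are stripped before lookup — classification applies to descriptors.
    """

    addresses: dict[str, frozenset[TreeAddress]] = field(default_factory=dict)
    strict: bool = True
    _category_cache: dict[str, frozenset[Category]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for name, addrs in self.addresses.items():
            if not addrs:
                raise ValueError(f"descriptor {name!r} has no tree addresses")

    def __len__(self) -> int:
        return len(self.addresses)

    def __contains__(self, descriptor: str) -> bool:
        return self._normalize(descriptor) in self.addresses

    @staticmethod
    def _normalize(descriptor: str) -> str:
        # "Descriptor/qualifier" → "Descriptor"; leading '*' marks a major
        # topic in MEDLINE exports and is not part of the name
        return descriptor.split("/", 1)[0].lstrip("*").strip()

    def lookup(self, descriptor: str) -> frozenset[TreeAddress]:
        name = self._normalize(descriptor)
        try:
            return self.addresses[name]
        except KeyError:
            if self.strict:
                raise UnknownDescriptorError(name) from None
            logger.warning("unknown MeSH descriptor (lenient mode): %r", name)
            return frozenset()

    def categories(self, descriptor: str) -> frozenset[Category]:
        """Category set of a descriptor (cached union over its addresses)."""
        name = self._normalize(descriptor)
        cached = self._category_cache.get(name)
        if cached is None:
            cats: set[Category] = set()
            for addr in self.lookup(name):
                cats |= classify_address(addr)
            cached = frozenset(cats)
            if name in self.addresses:
                self._category_cache[name] = cached
        return cached

    # ---- readers -------------------------------------------------------

    @classmethod
    def from_items(cls, items: Mapping[str, Iterable[str]], *,
                   strict: bool = True) -> "MeshVocabulary":
        return cls(
            {name: frozenset(TreeAddress(a) for a in addrs)
             for name, addrs in items.items()},
            strict=strict,
        )

    @classmethod
    def from_ascii(cls, path: str | Path, *, strict: bool = True) -> "MeshVocabulary":
        """Read the NLM ASCII descriptor format (``d####.bin`` files).

        Records are blank-line/``*NEWRECORD`` separated; the descriptor name
        is on ``MH = `` lines and each tree address on an ``MN = `` line.
        Descriptors without any ``MN`` line (check tags etc.) are skipped.
        """
        items: dict[str, set[str]] = {}
        name: str | None = None
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if line == "*NEWRECORD" or not line:
                name = None
                continue
            if line.startswith("MH = "):
                name = line[5:].strip()
                items.setdefault(name, set())
            elif line.startswith("MN = ") and name is not None:
                items[name].add(line[5:].strip())
        return cls.from_items(
            {n: a for n, a in items.items() if a}, strict=strict
        )

    @classmethod
    def from_tsv(cls, path: str | Path, *, strict: bool = True) -> "MeshVocabulary":
        """Read the two-column fixture dialect: ``descriptor<TAB>address``."""
        items: dict[str, set[str]] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            items.setdefault(parts[0], set()).add(parts[1])
        return cls.from_items(items, strict=strict)

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"{name}\t{addr}"
            for name in sorted(self.addresses)
            for addr in sorted(a.address for a in self.addresses[name])
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def classify_term(descriptor: str, vocab: MeshVocabulary) -> set[Category]:
    """Union of :func:`classify_address` over all addresses of a descriptor.

    A descriptor counts at most once per category however many of its
    addresses trigger that category.
    """
    return set(vocab.categories(descriptor))


#: Publication types that flag an article as clinical (trials of any phase,
#: clinical studies, and guidelines).
CLINICAL_PUB_TYPES = frozenset(
    {
        "clinical trial",
        "clinical trial, phase i",
        "clinical trial, phase ii",
        "clinical trial, phase iii",
        "clinical trial, phase iv",
        "clinical study",
        "guideline",
    }
)


def is_clinical_article(pub_types: Iterable[str]) -> bool:
    """True iff any publication type marks the article as clinical."""
    return any(pt.strip().lower() in CLINICAL_PUB_TYPES for pt in pub_types)


@dataclass
class ArticleRecord:
    """One corpus article: identity, year, MeSH terms, publication types.

    ``is_clinical`` may be supplied (e.g. from an upstream flagging run) or
    left ``None`` to be derived from ``pub_types``; when both are available
    they must agree.
    """

    article_id: str
    pub_year: int
    mesh_terms: list[str] = field(default_factory=list)
    pub_types: list[str] = field(default_factory=list)
    is_clinical: bool | None = None

    def __post_init__(self) -> None:
        derived = is_clinical_article(self.pub_types)
        if self.is_clinical is None:
            self.is_clinical = derived
        elif self.pub_types and self.is_clinical != derived:
            raise ValueError(
                f"article {self.article_id}: is_clinical={self.is_clinical} "
                f"contradicts pub_types {self.pub_types!r}"
            )


def category_counts(
    article: ArticleRecord, vocab: MeshVocabulary
) -> dict[Category, int]:
    """Count the distinct descriptors of an article in each category.

    Set semantics at the descriptor level: duplicate terms in the record are
    collapsed, and a descriptor contributes at most 1 per category.
    """
    counts = {cat: 0 for cat in Category}
    seen = {vocab._normalize(t) for t in article.mesh_terms}
    for term in seen:
        for cat in vocab.categories(term):
            counts[cat] += 1
    return counts


# ---- article JSON-lines I/O ------------------------------------------------

_ARTICLE_KEYS = ("article_id", "pub_year", "mesh_terms", "pub_types")


def read_articles_jsonl(path: str | Path) -> Iterator[ArticleRecord]:
    """Stream articles from JSON-lines (one object per line)."""
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            yield ArticleRecord(
                article_id=str(obj["article_id"]),
                pub_year=int(obj["pub_year"]),
                mesh_terms=list(obj.get("mesh_terms", [])),
                pub_types=list(obj.get("pub_types", [])),
                is_clinical=obj.get("is_clinical"),
            )


def write_articles_jsonl(articles: Iterable[ArticleRecord], path: str | Path) -> None:
    """Write articles as JSON-lines; round-trips bit-exactly with the reader."""
    with open(path, "w") as fh:
        for art in articles:
            obj = {k: getattr(art, k) for k in _ARTICLE_KEYS}
            obj["is_clinical"] = art.is_clinical
            fh.write(json.dumps(obj, sort_keys=False) + "\n")
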