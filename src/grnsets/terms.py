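"""Combinatorial library of Hill-type production terms and regulatory-network structures.

The three-gene network under study (*eud-1*, *nhr-40*, *sult-1* in the nematode
*Pristionchus pacificus*) is modelled by mass-action transcription/translation
ODEs in which the only structural unknown is the mRNA production term of each
gene: a product of one or two Hill factors (activation ``P/(K+P)`` or
repression ``K/(K+P)``) in the regulator proteins, with an optional squared
single factor for cooperativity.  Enumerating every admissible production term
per gene and taking the Cartesian product over genes yields the full
combinatorial family of candidate network structures: 24 terms per gene and
24**3 = 13,824 wild-type models; knock-out families restrict the regulators to
the surviving proteins (12 terms per gene, 12**2 = 144 models).

This module owns that enumeration: a canonical, deterministic term ordering, a
mixed-radix integer index over structures, knock-out reduction, and the
handful of named structures used throughout the analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterator, Mapping, Optional

GENES = ("eud-1", "nhr-40", "sult-1")
REGULATORS = ("E", "N", "S")
PROTEIN_OF_GENE = dict(zip(GENES, REGULATORS))
GENE_OF_PROTEIN = dict(zip(REGULATORS, GENES))
#: 1-based gene position fixing the half-max numbering: gene at position i uses
#: K_i for its (first) Hill factor and K_{i+3} for the second factor of a pair.
GENE_POSITION = {g: i + 1 for i, g in enumerate(GENES)}

ACTIVATION = "activation"
REPRESSION = "repression"
SIGNS = (ACTIVATION, REPRESSION)


class TermLibraryError(ValueError):
    """Raised for invalid terms, indices or knock-out requests."""


@dataclass(frozen=True)
class ProductionTerm:
    """One Hill-type mRNA production factor.

    ``factors`` is an ordered tuple of 1-2 ``(regulator, sign)`` pairs with
    ``regulator`` in {"E", "N", "S"} and ``sign`` activation/repression.
    ``exponent`` is 1, or 2 for a squared (cooperative) single factor.
    """

    factors: tuple[tuple[str, str], ...]
    exponent: int = 1

    def __post_init__(self) -> None:
        if not 1 <= len(self.factors) <= 2:
            raise TermLibraryError(f"term must have 1 or 2 factors, got {len(self.factors)}")
        for reg, sign in self.factors:
            if reg not in REGULATORS:
                raise TermLibraryError(f"unknown regulator {reg!r}")
            if sign not in SIGNS:
                raise TermLibraryError(f"unknown sign {sign!r}")
        if len(self.factors) == 2:
            if self.exponent != 1:
                raise TermLibraryError("two-factor terms must have exponent 1")
            if self.factors[0][0] == self.factors[1][0]:
                raise TermLibraryError("two-factor terms need distinct regulators")
        elif self.exponent not in (1, 2):
            raise TermLibraryError(f"exponent must be 1 or 2, got {self.exponent}")

    @property
    def regulators(self) -> frozenset[str]:
        return frozenset(reg for reg, _ in self.factors)

    def describe(self) -> str:
        parts = []
        for reg, sign in self.factors:
            symbol = "act" if sign == ACTIVATION else "rep"
            parts.append(f"{symbol}({reg})")
        body = "*".join(parts)
        return f"{body}^2" if self.exponent == 2 else body


def enumerate_terms(available_regulators) -> list[ProductionTerm]:
    """Canonical ordered list of admissible production terms.

    Ordering (deterministic, documented): first the ``2r`` single Hill terms
    (regulator order E, N, S; activation before repression), then the ``2r``
    squared single terms in the same order, then the ``4 * C(r, 2)`` two-factor
    products (pair order (E,N), (E,S), (N,S); sign order act*act, act*rep,
    rep*act, rep*rep), where ``r`` is the number of available regulators.
    """
    regs = [r for r in REGULATORS if r in set(available_regulators)]
    if not regs:
        raise TermLibraryError("at least one regulator is required")
    if len(regs) != len(set(available_regulators)):
        unknown = set(available_regulators) - set(REGULATORS)
        raise TermLibraryError(f"unknown regulators: {sorted(unknown)}")
    terms: list[ProductionTerm] = []
    for exponent in (1, 2):
        for reg in regs:
            for sign in SIGNS:
                terms.append(ProductionTerm(((reg, sign),), exponent=exponent))
    for r1, r2 in combinations(regs, 2):
        for s1 in SIGNS:
            for s2 in SIGNS:
                terms.append(ProductionTerm(((r1, s1), (r2, s2))))
    return terms


@dataclass
class RegulatoryModel:
    """A single network structure: one production term per modelled gene.

    ``terms[gene]`` may be ``None`` after a knock-out reduction removed every
    factor of that gene's term, leaving basal transcription only.
    """

    terms: dict[str, Optional[ProductionTerm]]
    knockout: Optional[str] = None
    model_index: Optional[int] = None

    def __post_init__(self) -> None:
        for gene in self.terms:
            if gene not in GENES:
                raise TermLibraryError(f"unknown gene {gene!r}")
        if self.knockout is not None:
            if self.knockout not in GENES:
                raise TermLibraryError(f"unknown knockout gene {self.knockout!r}")
            if self.knockout in self.terms:
                raise TermLibraryError("knocked-out gene cannot retain a production term")
            ko_protein = PROTEIN_OF_GENE[self.knockout]
            for gene, term in self.terms.items():
                if term is not None and ko_protein in term.regulators:
                    raise TermLibraryError(
                        f"{gene} term references knocked-out protein {ko_protein}"
                    )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g in GENES if g in self.terms)

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(PROTEIN_OF_GENE[g] for g in self.genes)

    def structure_equal(self, other: "RegulatoryModel") -> bool:
        return self.terms == other.terms and self.knockout == other.knockout

    def to_json(self) -> str:
        doc = {
            "knockout": self.knockout,
            "terms": {
                gene: None
                if term is None
                else {"factors": [list(f) for f in term.factors], "exponent": term.exponent}
                for gene, term in self.terms.items()
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RegulatoryModel":
        doc = json.loads(text)
        terms: dict[str, Optional[ProductionTerm]] = {}
        for gene, spec in doc["terms"].items():
            if spec is None:
                terms[gene] = None
            else:
                terms[gene] = ProductionTerm(
                    tuple(tuple(f) for f in spec["factors"]), exponent=spec.get("exponent", 1)
                )
        return cls(terms=terms, knockout=doc.get("knockout"))


@dataclass(frozen=True)
class ModelFamily:
    """The combinatorial family of structures over a fixed gene/regulator set."""

    available_regulators: frozenset[str]
    target_genes: tuple[str, ...]
    knockout: Optional[str] = None
    terms: tuple[ProductionTerm, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(enumerate_terms(self.available_regulators)))

    @property
    def terms_per_gene(self) -> int:
        r = len(self.available_regulators)
        return 4 * r + 4 * comb(r, 2)

    @property
    def size(self) -> int:
        return self.terms_per_gene ** len(self.target_genes)

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterator[RegulatoryModel]:
        for index in range(self.size):
            yield model_from_index(self, index)


_INFER = "__infer__"


def build_family(available_regulators, target_genes, knockout: Optional[str] = _INFER) -> ModelFamily:
    """Build the family of all structures over ``target_genes``.

    The per-gene term count is ``4r + 4*C(r,2)`` for ``r`` available
    regulators (24 for the full wild-type network, 12 after one knock-out) and
    the family size is that count raised to the number of target genes
    (24**3 = 13,824 wild-type structures, 12**2 = 144 per knock-out).
    Iteration is lazy; parameter sets are never materialised here.  By
    default a single missing gene is interpreted as the knocked-out gene.
    """
    genes = tuple(g for g in GENES if g in set(target_genes))
    if not genes:
        raise TermLibraryError("at least one target gene is required")
    if len(genes) != len(set(target_genes)):
        raise TermLibraryError(f"unknown target genes in {sorted(set(target_genes))}")
    if knockout == _INFER:
        missing = set(GENES) - set(genes)
        knockout = missing.pop() if len(missing) == 1 else None
    if knockout is not None:
        if knockout in genes:
            raise TermLibraryError(f"knocked-out gene {knockout} cannot be a target gene")
        if PROTEIN_OF_GENE[knockout] in set(available_regulators):
            raise TermLibraryError(
                f"regulator {PROTEIN_OF_GENE[knockout]} is inconsistent with dropped gene {knockout}"
            )
    return ModelFamily(
        available_regulators=frozenset(available_regulators),
        target_genes=genes,
        knockout=knockout,
    )


def wild_type_family() -> ModelFamily:
    return build_family(REGULATORS, GENES)


def model_from_index(family: ModelFamily, index: int) -> RegulatoryModel:
    """Decode a 0-based mixed-radix index into a structure.

    ``index = i_1 * b**(k-1) + ... + i_k`` with base ``b = terms_per_gene`` and
    digit order following the canonical gene order (eud-1, nhr-40, sult-1).
    """
    if not 0 <= index < family.size:
        raise TermLibraryError(f"index {index} out of range [0, {family.size})")
    base = family.terms_per_gene
    digits = []
    rest = index
    for _ in family.target_genes:
        digits.append(rest % base)
        rest //= base
    digits.reverse()
    terms = {gene: family.terms[d] for gene, d in zip(family.target_genes, digits)}
    return RegulatoryModel(terms=terms, knockout=family.knockout, model_index=index)


def index_of_model(family: ModelFamily, model: RegulatoryModel) -> int:
    """Inverse of :func:`model_from_index`; exact round-trip."""
    if tuple(model.genes) != family.target_genes:
        raise TermLibraryError("model genes do not match the family's target genes")
    base = family.terms_per_gene
    index = 0
    for gene in family.target_genes:
        term = model.terms[gene]
        if term is None:
            raise TermLibraryError(f"{gene} has no production term; not a family member")
        try:
            digit = family.terms.index(term)
        except ValueError:
            raise TermLibraryError(f"{gene} term {term.describe()} not in family library")
        index = index * base + digit
    return index


def _reduce_term(term: Optional[ProductionTerm], ko_protein: str) -> Optional[ProductionTerm]:
    if term is None:
        return None
    kept = tuple(f for f in term.factors if f[0] != ko_protein)
    if not kept:
        return None  # pure function of the removed protein: basal production only
    if kept == term.factors:
        return term
    return ProductionTerm(kept, exponent=1)


def reduce_for_knockout(model_or_family, gene: str):
    """Knock a gene out of a model or a whole family.

    The knocked-out gene's equations are dropped and every Hill factor in the
    knocked-out protein is removed from the surviving genes' terms.  A term
    that was a pure function of the removed protein collapses to ``None``
    (basal transcription only).  For a family, the term library shrinks to the
    terms over the surviving regulators.
    """
    if gene not in GENES:
        raise TermLibraryError(f"unknown gene {gene!r}")
    ko_protein = PROTEIN_OF_GENE[gene]
    if isinstance(model_or_family, ModelFamily):
        family = model_or_family
        if gene not in family.target_genes:
            raise TermLibraryError(f"{gene} is not in the family")
        return build_family(
            family.available_regulators - {ko_protein},
            tuple(g for g in family.target_genes if g != gene),
            knockout=gene,
        )
    model = model_or_family
    if gene not in model.terms:
        raise TermLibraryError(f"{gene} is not in the model")
    terms = {
        g: _reduce_term(t, ko_protein) for g, t in model.terms.items() if g != gene
    }
    return RegulatoryModel(terms=terms, knockout=gene, model_index=None)


def _act(*regs: str) -> ProductionTerm:
    return ProductionTerm(tuple((r, ACTIVATION) for r in regs))


def _rep(*regs: str) -> ProductionTerm:
    return ProductionTerm(tuple((r, REPRESSION) for r in regs))


def named_models() -> dict[str, RegulatoryModel]:
    """Reference structures used throughout the analysis.

    ``model_11574`` is the structure used as ground truth in the synthetic
    misspecification study; ``unified`` is the structure found in the
    intersection of the per-experiment model sets.  The remaining entries are
    this package's misspecified candidates: ``near_11574`` shares most of the
    truth's structural features, while ``distant_rich`` and ``distant_minimal``
    share none of them (all-repression structures of high and low complexity).
    """
    models = {
        "model_11574": RegulatoryModel(
            terms={
                "eud-1": _act("N", "S"),
                "nhr-40": _act("N"),
                "sult-1": ProductionTerm((("E", ACTIVATION),), exponent=2),
            }
        ),
        "unified": RegulatoryModel(
            terms={
                "eud-1": _act("E", "N"),
                "nhr-40": _act("E", "N"),
                "sult-1": _act("N", "S"),
            }
        ),
        "near_11574": RegulatoryModel(
            terms={
                "eud-1": _act("N", "S"),
                "nhr-40": ProductionTerm((("N", ACTIVATION),), exponent=2),
                "sult-1": _act("E"),
            }
        ),
        "distant_rich": RegulatoryModel(
            terms={
                "eud-1": ProductionTerm((("E", REPRESSION),), exponent=2),
                "nhr-40": _rep("E", "S"),
                "sult-1": _rep("N", "S"),
            }
        ),
        "distant_minimal": RegulatoryModel(
            terms={
                "eud-1": _rep("E"),
                "nhr-40": _rep("S"),
                "sult-1": _rep("S"),
            }
        ),
    }
    family = wild_type_family()
    for model in models.values():
        model.model_index = index_of_model(family, model)
    return models
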