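"""Prioritization of candidate function-shifting substitutions.

Given the reconstructed ancestral sequence at the base of a branch and the
derived sequence at its end, every differing site is a candidate for
having caused the functional shift on that branch. Candidates are then
whittled down: substitutions whose derived state is shared with an
independent reconstruction (and therefore cannot explain a functional
difference between the two reconstructions) are set aside; the remainder
are partitioned into biochemically conservative and radical replacements;
ligand-contacting positions (an externally supplied structural
annotation) are flagged separately. Radical, non-contacting, non-shared
substitutions are the prioritized large-effect candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from Bio.Align import substitution_matrices

from .io import Alignment


class ScreenError(ValueError):
    pass


@dataclass
class Substitution:
    """One historical replacement, labelled A<site>B with 1-based sites."""

    site: int
    ancestral: str
    derived: str
    shared_with_other_recon: bool = False
    conservative: bool | None = None
    ligand_contacting: bool = False

    def __post_init__(self) -> None:
        if self.ancestral == self.derived:
            raise ScreenError(f"site {self.site}: ancestral and derived states equal")

    @property
    def label(self) -> str:
        return f"{self.ancestral}{self.site}{self.derived}"


def diff_sequences(seq_a: str, seq_b: str) -> list[Substitution]:
    """Substitutions from ``seq_a`` to ``seq_b``, skipping gapped sites."""
    if len(seq_a) != len(seq_b):
        raise ScreenError(f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}")
    subs = []
    for i, (a, b) in enumerate(zip(seq_a.upper(), seq_b.upper()), start=1):
        if a in "-X" or b in "-X":
            continue
        if a != b:
            subs.append(Substitution(site=i, ancestral=a, derived=b))
    return subs


class ConservativeRule:
    """Decide whether a replacement is biochemically conservative.

    Default: BLOSUM62 score of the unordered pair >= +1, which makes the
    canonical conservative pairs (D/E, I/L, K/R, S/T) conservative and
    leaves V/A, R/H and C/S radical. An explicit set of unordered pairs
    overrides the matrix."""

    def __init__(
        self,
        pairs: set[frozenset[str]] | None = None,
        matrix: str = "BLOSUM62",
        min_score: float = 1.0,
    ):
        self.pairs = pairs
        self.min_score = min_score
        self._matrix = None if pairs is not None else substitution_matrices.load(matrix)

    @classmethod
    def from_pair_list(cls, pairs: list[str]) -> "ConservativeRule":
        """Build from strings like "D/E" or "DE"."""
        parsed = set()
        for p in pairs:
            letters = [c for c in p.upper() if c.isalpha()]
            if len(letters) != 2:
                raise ScreenError(f"cannot parse residue pair {p!r}")
            parsed.add(frozenset(letters))
        return cls(pairs=parsed)

    def __call__(self, ancestral: str, derived: str) -> bool:
        from .io import AMINO_ACIDS

        a, b = ancestral.upper(), derived.upper()
        if a not in AMINO_ACIDS or b not in AMINO_ACIDS:
            raise ScreenError(f"unknown residue in pair {a}/{b}")
        if self.pairs is not None:
            return frozenset((a, b)) in self.pairs
        return float(self._matrix[a, b]) >= self.min_score


def classify_conservative(
    sub: Substitution, rule: ConservativeRule | None = None
) -> bool:
    rule = rule or ConservativeRule()
    return rule(sub.ancestral, sub.derived)


def packaged_contact_sites() -> set[int]:
    """Ligand-contacting alignment positions shipped as an annotation
    fixture (positions within contact distance of the bound steroid,
    derived externally from receptor crystal structures)."""
    text = (resources.files("ancres") / "data" / "contact_sites.txt").read_text()
    return {
        int(tok)
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
        for tok in line.split()
    }


@dataclass
class PrioritizationReport:
    """Every candidate substitution with its filter fate, plus counts.

    Filters, applied in order: (1) drop substitutions whose derived state
    is shared with the other reconstruction; (2) partition the unique
    remainder into conservative vs radical; (3) flag ligand-contacting
    positions. The final partitions are order-independent; the ordering
    only determines which counts are reported at each step.
    """

    substitutions: list[Substitution] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.substitutions)

    @property
    def n_shared(self) -> int:
        return sum(s.shared_with_other_recon for s in self.substitutions)

    @property
    def n_unique(self) -> int:
        return self.n_total - self.n_shared

    @property
    def n_conservative(self) -> int:
        return sum(
            bool(s.conservative)
            for s in self.substitutions
            if not s.shared_with_other_recon
        )

    @property
    def n_radical(self) -> int:
        return self.n_unique - self.n_conservative

    @property
    def prioritized(self) -> list[Substitution]:
        """Unique, radical, non-ligand-contacting candidates."""
        return [
            s
            for s in self.substitutions
            if not s.shared_with_other_recon
            and not s.conservative
            and not s.ligand_contacting
        ]

    def rows(self) -> list[dict]:
        out = []
        for s in self.substitutions:
            if s.shared_with_other_recon:
                fate = "shared"
            elif s.conservative:
                fate = "conservative"
            elif s.ligand_contacting:
                fate = "ligand-contacting"
            else:
                fate = "prioritized"
            out.append(
                {
                    "label": s.label,
                    "site": s.site,
                    "ancestral": s.ancestral,
                    "derived": s.derived,
                    "shared_with_other_recon": s.shared_with_other_recon,
                    "conservative": bool(s.conservative),
                    "ligand_contacting": s.ligand_contacting,
                    "fate": fate,
                }
            )
        return out


def prioritize(
    subs: list[Substitution],
    other_recon_seq: str | None = None,
    contact_sites: set[int] | None = None,
    rule: ConservativeRule | None = None,
) -> PrioritizationReport:
    """Run the candidate filter cascade and report every substitution's fate.

    ``other_recon_seq`` is the independent reconstruction of the same
    ancestor used for the shared-derived-state filter; ``contact_sites``
    are 1-based ligand-contacting positions."""
    rule = rule or ConservativeRule()
    contact_sites = contact_sites if contact_sites is not None else set()
    annotated = []
    for s in subs:
        shared = False
        if other_recon_seq is not None:
            if s.site > len(other_recon_seq):
                raise ScreenError(
                    f"site {s.site} beyond the comparison sequence "
                    f"({len(other_recon_seq)} sites)"
                )
            shared = other_recon_seq[s.site - 1].upper() == s.derived
        annotated.append(
            Substitution(
                site=s.site,
                ancestral=s.ancestral,
                derived=s.derived,
                shared_with_other_recon=shared,
                conservative=rule(s.ancestral, s.derived),
                ligand_contacting=s.site in contact_sites,
            )
        )
    return PrioritizationReport(substitutions=annotated)


def screen_alignment_pair(
    ancestor: Alignment | str,
    derived: Alignment | str,
    other: Alignment | str | None = None,
    contact_sites: set[int] | None = None,
    rule: ConservativeRule | None = None,
) -> PrioritizationReport:
    """Convenience wrapper taking sequences or single-sequence alignments."""

    def as_seq(x):
        if x is None or isinstance(x, str):
            return x
        return x.sequence(x.names[0])

    subs = diff_sequences(as_seq(ancestor), as_seq(derived))
    return prioritize(subs, as_seq(other), contact_sites, rule)
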