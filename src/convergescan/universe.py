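"""Per-species annotated gene lists keyed by one-to-one ortholog IDs.

The cross-species unit of comparison is the ortholog key (an *A. thaliana*
style locus identifier): a gene is "the same" in two species iff it carries
the same key. Genes without a one-to-one ortholog are absent from the
universe and invisible to every downstream overlap statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple


class ConfigurationError(ValueError):
    """An infeasible or inconsistent configuration."""


@dataclass(frozen=True)
class OrthologUniverse:
    """Annotated gene backgrounds for a set of species.

    Parameters
    ----------
    species_ids
        Ordered species labels.
    annotated
        Mapping species -> frozenset of ortholog IDs annotated in that
        species. Each ID occurs at most once per species (one-to-one
        orthology).
    """

    species_ids: Tuple[str, ...]
    annotated: Mapping[str, frozenset]

    def __post_init__(self):
        missing = [s for s in self.species_ids if s not in self.annotated]
        if missing:
            raise ConfigurationError(f"no gene list for species {missing}")

    def size(self, species: str) -> int:
        return len(self.annotated[species])

    def intersection(self, subset: Iterable[str] | None = None) -> frozenset:
        """Ortholog IDs annotated in every species of ``subset`` (default all)."""
        subset = tuple(subset) if subset is not None else self.species_ids
        if not subset:
            raise ValueError("empty species subset")
        out = frozenset(self.annotated[subset[0]])
        for s in subset[1:]:
            out &= self.annotated[s]
        return out

    @property
    def shared_core(self) -> frozenset:
        return self.intersection()

    def sorted_genes(self, species: str) -> Tuple[str, ...]:
        return tuple(sorted(self.annotated[species]))
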