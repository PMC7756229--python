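"""Published gene counts from the three-species Alpine Brassicaceae scans.

These are the printed set sizes of the comparative study system — *Arabis
alpina* (Aal), *Arabidopsis halleri* (Aha) and *Cardamine resedifolia*
(Cre), six Pool-Seq populations each across Alpine altitudinal gradients —
used as inputs for replication mode: the overlap resampling depends only on
annotated-background sizes, the shared ortholog core, per-species candidate
counts and the observed cross-species overlaps, all of which are public
summary counts. Where an overlap table and running text disagree by one
gene (Aha outliers 3,864 vs 3,863), the table value is used.

In replication mode all cross-species sharing is placed in the three-way
core (pairwise annotated overlaps are not published); three-way statistics
depend only on the core size and the per-species background sizes.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .simulate import SimConfig, gen_ortholog_universe
from .universe import OrthologUniverse

SPECIES: Tuple[str, str, str] = ("Aal", "Aha", "Cre")

#: Functionally annotated genes with one-to-one orthologs, per species.
ANNOTATED: Dict[str, int] = {"Aal": 15909, "Aha": 16088, "Cre": 16047}

#: Ortholog IDs annotated in all three species.
SHARED_CORE: int = 12485

#: Shared genes (all three species) containing nonsynonymous SNPs in all three.
NS_UNIVERSE_SHARED: int = 8681

ANALYSES: Tuple[str, ...] = (
    "outlier", "ASPVAL", "PRECYY", "SFROYY", "SLP25", "SRADYY", "SWB",
    "TAVEYY", "TWI25SS",
)

#: Candidate gene counts per analysis and species (genes with >=1 significant SNP).
CANDIDATE_SIZES: Dict[str, Dict[str, int]] = {
    "outlier": {"Aal": 1883, "Aha": 3864, "Cre": 670},
    "ASPVAL": {"Aal": 617, "Aha": 2894, "Cre": 5944},
    "PRECYY": {"Aal": 7386, "Aha": 4306, "Cre": 4627},
    "SFROYY": {"Aal": 2626, "Aha": 3118, "Cre": 3809},
    "SLP25": {"Aal": 6853, "Aha": 3053, "Cre": 5313},
    "SRADYY": {"Aal": 2954, "Aha": 4077, "Cre": 5842},
    "SWB": {"Aal": 5434, "Aha": 6196, "Cre": 4370},
    "TAVEYY": {"Aal": 5398, "Aha": 4302, "Cre": 2919},
    "TWI25SS": {"Aal": 4931, "Aha": 5577, "Cre": 5266},
}

#: Observed three-way shared candidate genes per analysis.
OBSERVED_SHARED: Dict[str, int] = {
    "outlier": 27, "ASPVAL": 47, "PRECYY": 586, "SFROYY": 123, "SLP25": 462,
    "SRADYY": 280, "SWB": 565, "TAVEYY": 283, "TWI25SS": 581,
}

#: Of the shared genes, how many contain nonsynonymous SNPs in all species.
SHARED_WITH_NS: Dict[str, int] = {
    "outlier": 21, "ASPVAL": 38, "PRECYY": 502, "SFROYY": 107, "SLP25": 399,
    "SRADYY": 247, "SWB": 504, "TAVEYY": 247, "TWI25SS": 488,
}

#: Shared genes whose nonsynonymous SNP is itself significant in the same
#: analysis in every species (per-analysis top candidates).
SHARED_WITH_FLAGGED_NS: Dict[str, int] = {
    "outlier": 1, "ASPVAL": 2, "PRECYY": 82, "SFROYY": 18, "SLP25": 50,
    "SRADYY": 21, "SWB": 81, "TAVEYY": 34, "TWI25SS": 90,
}

#: Observed pairwise shared candidate genes (Aal&Aha, Aha&Cre, Cre&Aal).
OBSERVED_PAIRWISE: Dict[str, Dict[Tuple[str, str], int]] = {
    "outlier": {("Aal", "Aha"): 422, ("Aha", "Cre"): 155, ("Cre", "Aal"): 80},
    "ASPVAL": {("Aal", "Aha"): 108, ("Aha", "Cre"): 1055, ("Cre", "Aal"): 239},
    "PRECYY": {("Aal", "Aha"): 1799, ("Aha", "Cre"): 1257, ("Cre", "Aal"): 2043},
    "SFROYY": {("Aal", "Aha"): 468, ("Aha", "Cre"): 764, ("Cre", "Aal"): 596},
    "SLP25": {("Aal", "Aha"): 1206, ("Aha", "Cre"): 988, ("Cre", "Aal"): 2189},
    "SRADYY": {("Aal", "Aha"): 681, ("Aha", "Cre"): 1506, ("Cre", "Aal"): 1049},
    "SWB": {("Aal", "Aha"): 1932, ("Aha", "Cre"): 1602, ("Cre", "Aal"): 1409},
    "TAVEYY": {("Aal", "Aha"): 1380, ("Aha", "Cre"): 826, ("Cre", "Aal"): 930},
    "TWI25SS": {("Aal", "Aha"): 1569, ("Aha", "Cre"): 1766, ("Cre", "Aal"): 1552},
}

#: Deduplicated across analyses: shared genes / with NS / top candidates.
UNIQUE_SHARED: int = 2050
UNIQUE_SHARED_WITH_NS: int = 1759
TOP_CANDIDATES: int = 298


def build_universe() -> OrthologUniverse:
    """Three-species ortholog universe with the published sizes.

    All cross-species sharing sits in the 12,485-gene three-way core; the
    remaining genes are species-private.
    """
    cfg = SimConfig(
        species_ids=SPECIES,
        annotated_sizes=tuple(ANNOTATED[s] for s in SPECIES),
        shared_all=SHARED_CORE,
    )
    return gen_ortholog_universe(cfg)
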