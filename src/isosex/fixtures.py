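"""Packaged isopod phylogeny and heterogametic-type table.

The 26-taxon chronogram covers 24 isopod-study taxa (22 terrestrial isopods
from nine families, the two *Porcellio dilatatus* subspecies among them, and
the aquatic isopod *Asellus aquaticus*) plus two non-isopod outgroups
(*Talitrus saltator*, *Cherax quadricarinatus*). Topology is encoded from
text-anchored clade statements: Porcellionidae sister to Trachelipodidae;
*Helleria brevicornis* (Tylidae) sister to all other terrestrial isopods;
Philosciidae paraphyletic by inclusion of *Oniscus asellus*; Armadillidiidae
(all *Armadillidium* plus *Eluma purpurascens*) monophyletic; an
(*A. siculorum*, *A. assimile*) clade. Within-genus branching order beyond
those anchors is a package choice; the parsimony transition counts are
insensitive to it because the XY tips inside the crown clade are terminal
singletons.

Node ages (My) use the printed median estimates where available — 307
(Oniscidea vs Asellota), 117 (crown Oniscidea), 66 (*Armadillo* split), 38
(Trachelipodidae vs Porcellionidae), 36 (crown of the Philosciidae+Oniscidae
grade), 35 (crown *Porcellio* + *Porcellionides*), 25 (crown
*Armadillidium*), 15 (*Oniscus* vs *Philoscia*). All other internal ages are
APPROXIMATE: interpolated evenly between the bracketing dated nodes (and
marked below). The outgroup ages (450/400) are likewise placeholders; the
outgroups are pruned before every reconstruction.

Heterogametic types follow the published per-species table: 10 ZW and 5 XY
among the 16 assessed species, *A. assimile* coded OTHER (its all-male
broods fit neither heterogametic prediction), and 8 species UNKNOWN.
"""

from __future__ import annotations

from importlib import resources

import dendropy

from .states import CharacterStates, Scheme
from .trees import parse_newick, prune_taxa

__all__ = [
    "OUTGROUPS",
    "TAXON_TABLE",
    "fixture_isopod_tree",
    "fixture_state_table",
    "prune_outgroups",
    "packaged_tree_text",
    "packaged_states_text",
]

OUTGROUPS = ("Talitrus_saltator", "Cherax_quadricarinatus")

# (species, family, heterogametic type); OTHER = distinct-but-uncharacterized.
TAXON_TABLE: tuple[tuple[str, str, str], ...] = (
    ("Armadillidium_maculatum", "Armadillidiidae", "ZW"),
    ("Armadillidium_simoni", "Armadillidiidae", "UNKNOWN"),
    ("Armadillidium_depressum", "Armadillidiidae", "ZW"),
    ("Armadillidium_granulatum", "Armadillidiidae", "ZW"),
    ("Armadillidium_siculorum", "Armadillidiidae", "UNKNOWN"),
    ("Armadillidium_assimile", "Armadillidiidae", "OTHER"),
    ("Armadillidium_versicolor", "Armadillidiidae", "UNKNOWN"),
    ("Armadillidium_vulgare", "Armadillidiidae", "ZW"),
    ("Armadillidium_tunisiense", "Armadillidiidae", "UNKNOWN"),
    ("Armadillidium_nasatum", "Armadillidiidae", "XY"),
    ("Eluma_purpurascens", "Armadillidiidae", "ZW"),
    ("Porcellio_dilatatus_petiti", "Porcellionidae", "ZW"),
    ("Porcellio_dilatatus_dilatatus", "Porcellionidae", "XY"),
    ("Porcellio_dispar", "Porcellionidae", "UNKNOWN"),
    ("Porcellio_scaber", "Porcellionidae", "ZW"),
    ("Porcellio_laevis", "Porcellionidae", "ZW"),
    ("Porcellionides_pruinosus", "Porcellionidae", "UNKNOWN"),
    ("Trachelipus_rathkei", "Trachelipodidae", "ZW"),
    ("Oniscus_asellus", "Oniscidae", "ZW"),
    ("Philoscia_muscorum", "Philosciidae", "UNKNOWN"),
    ("Chaetophiloscia_elongata", "Philosciidae", "UNKNOWN"),
    ("Armadillo_officinalis", "Armadillidae", "XY"),
    ("Helleria_brevicornis", "Tylidae", "XY"),
    ("Asellus_aquaticus", "Asellidae", "XY"),
)

# Nested (age, children) topology; strings are tips (age 0). Ages marked
# "approx" are even interpolations between the bracketing dated nodes.
_ARMADILLIDIUM = (
    25.0,  # printed (crown Armadillidium, fossil-calibrated)
    [
        "Armadillidium_nasatum",
        (
            20.833,  # approx
            [
                (
                    13.889,  # approx
                    [
                        "Armadillidium_vulgare",
                        (6.944, ["Armadillidium_tunisiense",  # approx
                                 "Armadillidium_versicolor"]),
                    ],
                ),
                (
                    16.667,  # approx
                    [
                        (8.333, ["Armadillidium_siculorum",  # approx
                                 "Armadillidium_assimile"]),
                        (
                            12.5,  # approx
                            [
                                "Armadillidium_granulatum",
                                (
                                    8.333,  # approx
                                    [
                                        "Armadillidium_depressum",
                                        (4.167, ["Armadillidium_simoni",  # approx
                                                 "Armadillidium_maculatum"]),
                                    ],
                                ),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ],
)

_PORCELLIONIDAE = (
    35.0,  # printed (crown Porcellio/Porcellionides, fossil-calibrated)
    [
        "Porcellionides_pruinosus",
        (
            26.25,  # approx
            [
                (
                    17.5,  # approx
                    [
                        "Porcellio_scaber",
                        (8.75, ["Porcellio_dilatatus_dilatatus",  # approx
                                "Porcellio_dilatatus_petiti"]),
                    ],
                ),
                (13.125, ["Porcellio_laevis", "Porcellio_dispar"]),  # approx
            ],
        ),
    ],
)

_PHILOSCIIDAE_GRADE = (
    36.0,  # printed (origin of the paraphyletic Philosciidae grade)
    [
        "Chaetophiloscia_elongata",
        (15.0, ["Philoscia_muscorum", "Oniscus_asellus"]),  # printed
    ],
)

_INGROUP = (
    307.0,  # printed (Oniscidea vs Asellota)
    [
        "Asellus_aquaticus",
        (
            117.0,  # printed (crown Oniscidea)
            [
                "Helleria_brevicornis",
                (
                    66.0,  # printed (Armadillo split)
                    [
                        "Armadillo_officinalis",
                        (
                            56.667,  # approx
                            [
                                _PHILOSCIIDAE_GRADE,
                                (
                                    47.333,  # approx
                                    [
                                        (36.167,  # approx
                                         ["Eluma_purpurascens", _ARMADILLIDIUM]),
                                        (38.0,  # printed (Trachelipodidae split)
                                         ["Trachelipus_rathkei", _PORCELLIONIDAE]),
                                    ],
                                ),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ],
)

_FULL = (
    450.0,  # approx (outgroups only; pruned before analyses)
    [
        "Cherax_quadricarinatus",
        (400.0, ["Talitrus_saltator", _INGROUP]),  # approx
    ],
)


def _to_newick(node, parent_age: float | None) -> str:
    if isinstance(node, str):
        return node if parent_age is None else f"{node}:{parent_age:.6f}"
    age, children = node
    inner = ",".join(_to_newick(c, age) for c in children)
    if parent_age is None:
        return f"({inner})"
    return f"({inner}):{parent_age - age:.6f}"


def fixture_newick(include_outgroups: bool = True) -> str:
    """Newick text of the packaged chronogram (branch lengths in My)."""
    root = _FULL if include_outgroups else _INGROUP
    return _to_newick(root, None) + ";"


def fixture_isopod_tree(include_outgroups: bool = True) -> dendropy.Tree:
    """The packaged 26-taxon chronogram (or the 24-tip isopod ingroup)."""
    return parse_newick(fixture_newick(include_outgroups))


def prune_outgroups(tree: dendropy.Tree) -> dendropy.Tree:
    """Remove the two non-isopod outgroups, re-rooting at the isopod crown."""
    return prune_taxa(tree, list(OUTGROUPS))


def fixture_state_table(scheme: Scheme = "three_state") -> CharacterStates:
    """Heterogametic types of the 24 isopod taxa under the given coding.

    Under ``two_state`` the OTHER code (*A. assimile*) folds into UNKNOWN;
    under ``three_state`` it is a third reachable state.
    """
    return CharacterStates(scheme, {sp: st for sp, _, st in TAXON_TABLE})


def packaged_tree_text() -> str:
    """Contents of the installed Newick data file (identical to the builder)."""
    return resources.files("isosex").joinpath("data/isopod_chronogram.nwk").read_text()


def packaged_states_text() -> str:
    """Contents of the installed state-table data file."""
    return resources.files("isosex").joinpath(
        "data/heterogamety_states.tsv"
    ).read_text()
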