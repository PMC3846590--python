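"""Taxonomy-based supertree grafting (phylomatic-style).

Species missing from a backbone phylogeny are attached as new tips at their
genus node when the backbone has one, falling back to the family node;
multiple attachments at a node form a polytomy. Genera are assumed
monophyletic. Species whose genus and family are both absent are reported as
unplaced and skipped with a warning, so incremental curation of the backbone
is possible without hard failures.

New tips carry no branch length; landmark dating (:mod:`phyloscape.dating`)
assigns ages afterwards — downstream metrics require a dated tree.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .tree import _label_of, tip_labels

logger = logging.getLogger(__name__)

__all__ = ["TaxonomyError", "read_taxonomy", "GraftReport", "graft_species"]

GROWTH_FORMS = ("freestanding", "climbing")


class TaxonomyError(ValueError):
    """Malformed species -> (genus, family, growth form) table."""


def read_taxonomy(source) -> pd.DataFrame:
    """Read a taxonomy table with columns species,genus,family,growth_form.

    ``source`` is a path or file-like. Species labels must be unique, genus
    and family nonempty, growth_form in {freestanding, climbing}. Returns a
    DataFrame indexed by species.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str)
    required = ["species", "genus", "family", "growth_form"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TaxonomyError(f"taxonomy table missing columns: {missing}")
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"].unique())
        raise TaxonomyError(f"duplicate species labels: {dupes}")
    for col in ("genus", "family"):
        bad = df[col].isna() | (df[col].str.strip() == "")
        if bad.any():
            raise TaxonomyError(
                f"empty {col} for species: {sorted(df.loc[bad, 'species'])}"
            )
    bad_form = ~df["growth_form"].isin(GROWTH_FORMS)
    if bad_form.any():
        raise TaxonomyError(
            f"growth_form must be one of {GROWTH_FORMS}; offending species: "
            f"{sorted(df.loc[bad_form, 'species'])}"
        )
    return df.set_index("species", verify_integrity=True)


@dataclass
class GraftReport:
    """Where each new species was attached."""

    at_genus: list[str] = field(default_factory=list)
    at_family: list[str] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)
    already_present: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"grafted {len(self.at_genus)} species at genus, "
            f"{len(self.at_family)} at family; {len(self.unplaced)} unplaced; "
            f"{len(self.already_present)} already in backbone"
        )


def graft_species(
    backbone: dendropy.Tree, taxa: pd.DataFrame
) -> tuple[dendropy.Tree, GraftReport]:
    """Attach each species in ``taxa`` to the backbone and return (tree, report).

    Attachment node: the internal node labelled with the species' genus if
    one exists, else the internal node labelled with its family. Species
    already present as tips are left untouched. Species with neither node
    available are skipped and listed in the report (a warning is logged).

    The output tip set is the backbone's tips plus every placed species;
    existing branch lengths are untouched and new tips carry none.
    """
    tree = backbone.clone(depth=1)
    # label -> internal node; tips are not valid graft points (a genus that
    # appears only as a tip cannot receive children without changing tip set)
    node_by_label: dict[str, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        lbl = _label_of(node)
        if lbl is not None:
            node_by_label.setdefault(lbl, node)

    present = set(tip_labels(tree))
    report = GraftReport()
    for species, row in taxa.iterrows():
        if species in present:
            report.already_present.append(species)
            continue
        target = node_by_label.get(row["genus"])
        if target is not None:
            report.at_genus.append(species)
        else:
            target = node_by_label.get(row["family"])
            if target is not None:
                report.at_family.append(species)
                logger.info("placed %s at family %s (genus %s absent)",
                            species, row["family"], row["genus"])
            else:
                report.unplaced.append(species)
                logger.warning("cannot place %s: genus %r and family %r absent",
                               species, row["genus"], row["family"])
                continue
        taxon = tree.taxon_namespace.require_taxon(label=species)
        child = dendropy.Node(taxon=taxon)
        target.add_child(child)
        present.add(species)
    tree.update_taxon_namespace()
    return tree, report
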