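"""Ligand-receptor spatial encounter probability and interaction bookkeeping.

The encounter statistic asks, per microenvironment (ME), what fraction of
subspots detect every component of a ligand-receptor pair simultaneously:
a subspot counts as a full overlap iff each ligand gene, each receptor
subunit, and (by default) each cofactor exceeds a detection threshold on
unit-rescaled expression (strict > 0.15).  Per-component partial counts are
also reported, mirroring the partial-coloring bookkeeping of multi-subunit
receptors.  Protein/complex names are resolved to gene symbols through an
alias table (e.g. VEGFR1 -> FLT1, VEGFR2 -> KDR) before counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: alias entries used in the study's LR index
DEFAULT_ALIASES: dict[str, list[str]] = {
    "VEGFR1": ["FLT1"],
    "VEGFR2": ["KDR"],
    "NPNT1": ["NPNT", "FRAS1", "FREM1", "FREM2"],
    "NPNT2": ["NPNT", "FRAS1", "FREM1", "FREM2"],
}


@dataclass(frozen=True)
class LRPair:
    pathway: str
    ligands: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    cofactors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.ligands or not self.receptor_subunits:
            raise ValueError("an LR pair needs at least one ligand and one receptor subunit")

    @property
    def components(self) -> tuple[str, ...]:
        return self.ligands + self.receptor_subunits + self.cofactors

    def resolve_aliases(self, aliases: dict[str, list[str]] | None = None) -> "LRPair":
        """Swap protein/complex names for their gene symbols (flattening
        multi-gene aliases into additional components)."""
        aliases = DEFAULT_ALIASES if aliases is None else aliases

        def _map(genes: tuple[str, ...]) -> tuple[str, ...]:
            out: list[str] = []
            for g in genes:
                out.extend(aliases.get(g, [g]))
            return tuple(dict.fromkeys(out))

        return replace(
            self,
            ligands=_map(self.ligands),
            receptor_subunits=_map(self.receptor_subunits),
            cofactors=_map(self.cofactors),
        )


@dataclass
class EncounterResult:
    """Per-ME full-overlap and per-component detection counts for one LR pair."""

    pair: LRPair
    table: pd.DataFrame          # index ME; columns n_subspots, full_overlap, fraction
    component_counts: pd.DataFrame   # index ME; one column per component gene
    threshold: float

    @property
    def overall_fraction(self) -> float:
        n = self.table["n_subspots"].sum()
        return float(self.table["full_overlap"].sum() / n) if n else float("nan")


def encounter_probability(
    rescaled: pd.DataFrame,
    lr: LRPair,
    me_labels: pd.Series,
    threshold: float = 0.15,
    aliases: dict[str, list[str]] | None = None,
    require_cofactors: bool = True,
) -> EncounterResult:
    """Fraction of subspots where an entire LR pair is detected, per ME.

    ``rescaled`` is genes x subspots on the unit-max [0, 1] scale.  A gene is
    detected where rescaled expression > ``threshold`` (strict).  Full
    overlap requires every ligand, every receptor subunit, and every
    cofactor (unless ``require_cofactors`` is False, in which case cofactors
    are reported but not required).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    pair = lr.resolve_aliases(aliases)
    missing = [g for g in pair.components if g not in rescaled.index]
    if missing:
        raise KeyError(f"unresolvable gene symbol(s) after aliasing: {missing}")
    me_labels = me_labels.reindex(rescaled.columns)
    detected = rescaled.loc[list(pair.components)].to_numpy() > threshold
    required = pair.ligands + pair.receptor_subunits + (
        pair.cofactors if require_cofactors else ()
    )
    req_rows = [pair.components.index(g) for g in required]
    full = detected[req_rows].all(axis=0)

    me_index = pd.Index(sorted(me_labels.dropna().unique()), name="ME")
    rows, comp_rows = [], []
    for me in me_index:
        sel = (me_labels == me).to_numpy()
        n = int(sel.sum())
        fo = int(full[sel].sum())
        rows.append({"n_subspots": n, "full_overlap": fo,
                     "fraction": fo / n if n else np.nan})
        comp_rows.append({g: int(detected[i, sel].sum())
                          for i, g in enumerate(pair.components)})
    table = pd.DataFrame(rows, index=me_index)
    comps = pd.DataFrame(comp_rows, index=me_index)
    return EncounterResult(pair, table, comps, threshold)


def filter_significant_interactions(
    table: pd.DataFrame,
    prob_col: str = "prob",
    pval_col: str = "pval",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep interactions with probability > 0 and p-value < alpha, when the
    table carries those columns; otherwise return it unchanged."""
    if prob_col in table.columns and pval_col in table.columns:
        return table[(table[prob_col] > 0) & (table[pval_col] < alpha)].copy()
    return table


def compare_interaction_tables(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> dict[str, object]:
    """Partition (LR pair, sender, receiver) triples into shared/unique bins.

    * ``shared``: identical triple present in both conditions;
    * ``unique_pair_a``/``unique_pair_b``: triples whose LR pair occurs only
      in that condition;
    * ``unique_cluster_pairing_a``/``..._b``: triples of an LR pair present
      in both conditions but used by a sender/receiver pairing unique to one.
    Duplicate triples within a table are deduplicated with a warning note.
    """
    def _triples(tab: pd.DataFrame, tag: str) -> set[tuple[str, str, str]]:
        cols = ["lr_pair", "sender", "receiver"]
        for c in cols:
            if c not in tab.columns:
                raise KeyError(f"interaction table missing column {c!r}")
        trip = list(map(tuple, tab[cols].astype(str).to_numpy()))
        uniq = set(trip)
        if len(uniq) < len(trip):
            warnings.warn(
                f"{len(trip) - len(uniq)} duplicate triples in table {tag}; deduplicated",
                stacklevel=3,
            )
        return uniq

    a, b = _triples(table_a, "A"), _triples(table_b, "B")
    pairs_a = {t[0] for t in a}
    pairs_b = {t[0] for t in b}
    shared = a & b
    only_a, only_b = a - b, b - a
    unique_pair_a = {t for t in only_a if t[0] not in pairs_b}
    unique_pair_b = {t for t in only_b if t[0] not in pairs_a}
    unique_pairing_a = only_a - unique_pair_a
    unique_pairing_b = only_b - unique_pair_b
    bins = {
        "shared": shared,
        "unique_pair_a": unique_pair_a,
        "unique_pair_b": unique_pair_b,
        "unique_cluster_pairing_a": unique_pairing_a,
        "unique_cluster_pairing_b": unique_pairing_b,
    }
    bins["counts"] = {k: len(v) for k, v in bins.items()}
    return bins


def lr_table_to_pairs(table: pd.DataFrame) -> list[LRPair]:
    """Parse an LR database table (pathway, ligand, receptor_subunits,
    cofactors; multi-gene fields semicolon-joined) into LRPair objects."""
    pairs = []
    for _, row in table.iterrows():
        def _split(value: object) -> tuple[str, ...]:
            if value is None or (isinstance(value, float) and np.isnan(value)):
                return ()
            return tuple(g for g in str(value).split(";") if g)

        pairs.append(
            LRPair(
                pathway=str(row["pathway"]),
                ligands=_split(row["ligand"]),
                receptor_subunits=_split(row["receptor_subunits"]),
                cofactors=_split(row.get("cofactors", "")),
            )
        )
    return pairs
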