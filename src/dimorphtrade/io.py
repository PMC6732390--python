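"""Data model and I/O: specimen tables, Newick phylogenies, species matching.

A specimen table is a :class:`pandas.DataFrame` with one row per fish and
the canonical columns ``specimen_id``, ``species``, ``sex``,
``standard_length`` (mm), ``raker_length`` (mm, mean of the measured gill
rakers), ``d13C``, ``d15N`` (per mil) and ``breeding_mode``. Phylogenies are
rooted dendropy trees with mandatory branch lengths, wrapped in
:class:`Phylogeny`.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

SEXES = ("female", "male", "unknown")
BREEDING_MODES = ("uniparental", "biparental", "nonmouthbrooding")

#: canonical column -> default header in delimited files
DEFAULT_SCHEMA = {
    "specimen_id": "specimen_id",
    "species": "species",
    "sex": "sex",
    "standard_length": "standard_length",
    "raker_lengths": ["raker_1", "raker_2", "raker_3"],
    "d13C": "d13C",
    "d15N": "d15N",
    "breeding_mode": "breeding_mode",
}


class ValidationError(ValueError):
    """Raised when a table violates a hard invariant (with offending rows)."""


def normalize_species(name: str) -> str:
    """Normalize a species label for matching: casefold, spaces -> underscores."""
    return str(name).strip().casefold().replace(" ", "_")


@dataclass
class TableReport:
    """What happened while reading a specimen table."""

    n_read: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"rows read: {self.n_read}", f"rows accepted: {self.n_accepted}"]
        for idx, reason in self.rejected:
            lines.append(f"  rejected row {idx}: {reason}")
        return "\n".join(lines)


def read_specimen_table(path, schema: dict | None = None, sep: str | None = None):
    """Read and validate a delimited specimen table.

    Parameters
    ----------
    path : str | Path | file-like
        Delimited text file with a header row. Comma or tab separated
        (sniffed unless `sep` is given).
    schema : dict, optional
        Mapping from canonical column names to the file's header names;
        ``raker_lengths`` maps to a list of 1-3 columns. Missing keys fall
        back to :data:`DEFAULT_SCHEMA`.
    sep : str, optional
        Field separator; default sniffs ``,`` vs tab.

    Returns
    -------
    (DataFrame, TableReport)
        Canonical table (``raker_length`` is the arithmetic mean of the
        available per-specimen raker measurements) and a row-level report.
        Rows with missing/unusable species or standard length are rejected
        and listed in the report.

    Raises
    ------
    ValidationError
        If a required column is absent, a raker measurement is nonpositive
        or exceeds the specimen's standard length, sex or breeding mode has
        an unknown level, or breeding mode varies within a species.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    raw = pd.read_csv(path, sep=sep, engine="python")
    raw.columns = [c.strip() for c in raw.columns]

    required = ["specimen_id", "species", "sex", "standard_length", "d13C", "d15N",
                "breeding_mode"]
    missing = [sch[k] for k in required if sch[k] not in raw.columns]
    raker_cols = [c for c in sch["raker_lengths"] if c in raw.columns]
    if not raker_cols:
        missing.append("/".join(sch["raker_lengths"]))
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")

    df = pd.DataFrame(
        {
            "specimen_id": raw[sch["specimen_id"]].astype(str),
            "species": raw[sch["species"]],
            "sex": raw[sch["sex"]].astype(str).str.strip().str.lower(),
            "standard_length": pd.to_numeric(raw[sch["standard_length"]], errors="coerce"),
            "d13C": pd.to_numeric(raw[sch["d13C"]], errors="coerce"),
            "d15N": pd.to_numeric(raw[sch["d15N"]], errors="coerce"),
            "breeding_mode": raw[sch["breeding_mode"]].astype(str).str.strip().str.lower(),
        }
    )
    rakers = raw[raker_cols].apply(pd.to_numeric, errors="coerce")
    df["raker_length"] = rakers.mean(axis=1, skipna=True)

    report = TableReport(n_read=len(df))

    # hard invariants -> error listing offending rows
    bad_raker = rakers.le(0).any(axis=1)
    if bad_raker.any():
        rows = list(df.index[bad_raker])
        raise ValidationError(f"nonpositive gill raker length in rows {rows}")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValidationError(
            f"unknown sex level in rows {list(df.index[bad_sex])}; expected one of {SEXES}"
        )
    bad_mode = ~df["breeding_mode"].isin(BREEDING_MODES)
    if bad_mode.any():
        raise ValidationError(
            f"unknown breeding mode in rows {list(df.index[bad_mode])}; "
            f"expected one of {BREEDING_MODES}"
        )

    # soft filters -> reject rows with report
    keep = pd.Series(True, index=df.index)
    for idx in df.index:
        sp = df.at[idx, "species"]
        sl = df.at[idx, "standard_length"]
        if pd.isna(sp) or str(sp).strip() == "":
            report.rejected.append((int(idx), "missing species"))
            keep[idx] = False
        elif pd.isna(sl):
            report.rejected.append((int(idx), "missing standard length"))
            keep[idx] = False
        elif sl <= 0:
            report.rejected.append((int(idx), f"nonpositive standard length ({sl})"))
            keep[idx] = False
        elif pd.isna(df.at[idx, "raker_length"]):
            report.rejected.append((int(idx), "no raker measurement"))
            keep[idx] = False
        elif df.at[idx, "raker_length"] >= sl:
            report.rejected.append(
                (int(idx), "raker length not smaller than standard length"))
            keep[idx] = False
    df = df.loc[keep].copy()
    df["species"] = df["species"].astype(str).str.strip()
    report.n_accepted = len(df)

    # breeding mode must be constant within species
    per_sp = df.groupby("species")["breeding_mode"].nunique()
    varying = list(per_sp.index[per_sp > 1])
    if varying:
        raise ValidationError(f"breeding mode varies within species: {varying}")

    return df.reset_index(drop=True), report


def write_specimen_table(df: pd.DataFrame, path) -> None:
    """Write a canonical specimen table back to CSV (single raker column)."""
    df.to_csv(path, index=False)


class Phylogeny:
    """Rooted phylogeny with branch lengths, thin wrapper around dendropy.

    Invariants checked at construction: unique tip labels, branch lengths on
    every non-root edge, no unifurcations. Ultrametricity is checked but
    only warned about.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                raise ValueError("tree has edges without branch lengths; lengths are required")
            if node.edge.length < 0:
                raise ValueError("negative branch length")
            if not node.is_leaf() and len(node.child_nodes()) < 2:
                raise ValueError("unifurcating internal node")
        d = self.depths()
        vals = np.array(list(d.values()))
        if vals.size and vals.max() > 0 and (vals.max() - vals.min()) > 1e-6 * vals.max():
            warnings.warn("tree is not ultrametric; proceeding anyway", stacklevel=2)

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip (root stem edge included if present)."""
        out = {}
        stem = self.tree.seed_node.edge.length or 0.0

        def walk(node, acc):
            for ch in node.child_nodes():
                a = acc + ch.edge.length
                if ch.is_leaf():
                    out[ch.taxon.label] = a
                else:
                    walk(ch, a)

        if self.tree.seed_node.is_leaf():  # degenerate single-tip tree
            out[self.tree.seed_node.taxon.label] = stem
        else:
            walk(self.tree.seed_node, stem)
        return out

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def prune_to(self, labels) -> "Phylogeny":
        """Return a copy restricted to `labels` (root-to-tip depths preserved)."""
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(list(labels))
        clone.purge_taxon_namespace()
        return Phylogeny(clone)


def read_newick(source) -> Phylogeny:
    """Parse a rooted Newick tree (from a path or a literal string).

    Branch lengths are mandatory; duplicate tips or malformed Newick raise.
    """
    text = None
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if s.lstrip().startswith("(") or ";" in s:
            text = s
        else:
            with open(s) as fh:
                text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"could not parse Newick: {exc}") from exc
    return Phylogeny(tree)


@dataclass
class PruneReport:
    """Species bookkeeping from reconciling data with a tree."""

    kept: list[str]
    dropped_tips: list[str]          # in tree, absent from data
    missing_from_tree: list[str]     # in data, absent from tree (dropped from
                                     # phylogenetic analyses only)


def match_and_prune(tree: Phylogeny, species) -> tuple[Phylogeny, PruneReport]:
    """Restrict `tree` to the species present in the data.

    Matching is case-insensitive with spaces/underscores unified. Species in
    the data but absent from the tree are reported (they stay in
    non-phylogenetic analyses, mirroring how a species missing from a
    published tree is handled).
    """
    species = list(species)
    tip_by_norm = {normalize_species(l): l for l in tree.tip_labels}
    kept_tips, kept_species, missing = [], [], []
    for sp in species:
        n = normalize_species(sp)
        if n in tip_by_norm:
            kept_tips.append(tip_by_norm[n])
            kept_species.append(sp)
        else:
            missing.append(sp)
    if not kept_tips:
        raise ValueError("no overlap between tree tips and data species")
    dropped = [l for l in tree.tip_labels if l not in set(kept_tips)]
    pruned = tree.prune_to(kept_tips) if dropped else tree
    return pruned, PruneReport(kept=kept_species, dropped_tips=dropped,
                               missing_from_tree=missing)


def data_quality_report(df: pd.DataFrame, report: TableReport) -> str:
    """Human-readable validation summary for the CLI `validate` subcommand."""
    buf = _io.StringIO()
    print(f"specimens read:     {report.n_read}", file=buf)
    print(f"specimens accepted: {report.n_accepted}", file=buf)
    for idx, reason in report.rejected:
        print(f"  rejected row {idx}: {reason}", file=buf)
    print(f"species:            {df['species'].nunique()}", file=buf)
    by_mode = df.drop_duplicates("species")["breeding_mode"].value_counts()
    for mode, n in by_mode.items():
        print(f"  {mode:<18} {n} species", file=buf)
    sexed = df[df["sex"].isin(("female", "male"))]
    per_sp = sexed.groupby(["species", "sex"]).size().unstack(fill_value=0)
    ok = per_sp[(per_sp.get("female", 0) >= 2) & (per_sp.get("male", 0) >= 2)]
    print(f"species testable for dimorphism (>=2 per sex): {len(ok)}", file=buf)
    return buf.getvalue()
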