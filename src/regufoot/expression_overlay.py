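"""Differential-expression cross-tabulation and regulon concordance.

Input is a gene x condition matrix of replicate-averaged log2 expression
values.  A gene is differentially expressed (DE) for an ordered condition
pair when its log2 fold change (difference of stored log2 values) strictly
exceeds the threshold (default >2.0, i.e. >4-fold); the closed band
[1.5, 2.0] is reported separately as "moderate".  The cross-tab mirrors the
familiar substrate x substrate table: cell (r, c) counts genes up on r
versus c, with a parenthetical subcount of regulon members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def load_expression(path) -> pd.DataFrame:
    """Read a genes x conditions TSV of log2 expression values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def validate_expression(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


def log2fc(df: pd.DataFrame, cond_a: str, cond_b: str) -> pd.Series:
    """Per-gene log2 fold change of cond_a over cond_b (difference of log2 values)."""
    for c in (cond_a, cond_b):
        if c not in df.columns:
            raise KeyError(f"unknown condition {c!r}")
    return df[cond_a] - df[cond_b]


@dataclass
class DETable:
    """Pairwise DE counts with regulon subcounts and per-pair gene sets."""

    conditions: list[str]
    counts: pd.DataFrame  # cell (r, c): genes with log2fc(r, c) > threshold
    member_counts: pd.DataFrame
    de_sets: dict[tuple[str, str], set[str]]
    moderate_sets: dict[tuple[str, str], set[str]]
    union_up: set[str] = field(default_factory=set)
    threshold: float = 2.0
    moderate_band: tuple[float, float] = (1.5, 2.0)

    def to_tsv(self, path) -> None:
        """Counts with parenthetical regulon-member subcounts, one row per condition."""
        with open(path, "w") as fh:
            fh.write("condition\t" + "\t".join(self.conditions) + "\n")
            for r in self.conditions:
                cells = []
                for c in self.conditions:
                    if r == c:
                        cells.append("")
                    else:
                        cells.append(f"{self.counts.loc[r, c]} ({self.member_counts.loc[r, c]})")
                fh.write(r + "\t" + "\t".join(cells) + "\n")
            fh.write(f"# union of upregulated genes across all pairs: {len(self.union_up)}\n")


def de_crosstab(
    df: pd.DataFrame,
    threshold: float = 2.0,
    regulon_members: set[str] | None = None,
    moderate_band: tuple[float, float] = (1.5, 2.0),
) -> DETable:
    """Asymmetric cross-tab of DE gene counts over all ordered condition pairs.

    DE uses a strict inequality (log2fc > threshold); the moderate band is
    closed on both ends, so with the defaults a fold change of exactly 2.0
    is counted as moderate, not DE, and the two sets are disjoint.
    """
    if df.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    members = regulon_members or set()
    conds = list(df.columns)
    counts = pd.DataFrame(0, index=conds, columns=conds)
    mcounts = pd.DataFrame(0, index=conds, columns=conds)
    de_sets: dict[tuple[str, str], set[str]] = {}
    mod_sets: dict[tuple[str, str], set[str]] = {}
    union: set[str] = set()
    for r in conds:
        for c in conds:
            if r == c:
                continue
            fc = df[r] - df[c]
            de = set(df.index[fc > threshold])
            mod = set(df.index[(fc >= moderate_band[0]) & (fc <= moderate_band[1])])
            de_sets[(r, c)] = de
            mod_sets[(r, c)] = mod
            counts.loc[r, c] = len(de)
            mcounts.loc[r, c] = len(de & members)
            union |= de
    return DETable(
        conditions=conds,
        counts=counts,
        member_counts=mcounts,
        de_sets=de_sets,
        moderate_sets=mod_sets,
        union_up=union,
        threshold=threshold,
        moderate_band=moderate_band,
    )


@dataclass
class ConcordanceReport:
    regulon_id: str
    n_members: int
    n_assessable: int
    n_concordant: int
    concordance: float
    discordant: list[str]
    moderate_only: list[str]
    assessable: bool = True


def regulon_concordance(
    table: DETable,
    regulons: dict[str, set[str]],
    induction_map: dict[str, set[str]],
) -> dict[str, ConcordanceReport]:
    """Fraction of each regulon's members upregulated on their expected substrates.

    A member is concordant when it is DE for at least one (inducing,
    non-inducing) condition pair; members reaching only the moderate band on
    such pairs are listed separately.  Regulons with no member present in
    the matrix are reported as not assessable.
    """
    all_genes = set()
    for s in table.de_sets.values():
        all_genes |= s
    matrix_genes: set[str] = set()
    for (r, c), s in table.de_sets.items():
        matrix_genes |= s
    reports: dict[str, ConcordanceReport] = {}
    for rid in sorted(regulons):
        members = regulons[rid]
        inducing = induction_map.get(rid, set())
        non_inducing = [c for c in table.conditions if c not in inducing]
        present = sorted(members)
        if not present or not inducing or not non_inducing:
            reports[rid] = ConcordanceReport(rid, len(members), 0, 0, float("nan"), [], [], assessable=False)
            continue
        concordant, discordant, moderate_only = [], [], []
        for g in present:
            pairs = [(i, j) for i in inducing if i in table.conditions for j in non_inducing]
            if any(g in table.de_sets[p] for p in pairs):
                concordant.append(g)
            elif any(g in table.moderate_sets[p] for p in pairs):
                moderate_only.append(g)
            else:
                discordant.append(g)
        n = len(present)
        reports[rid] = ConcordanceReport(
            regulon_id=rid,
            n_members=n,
            n_assessable=n,
            n_concordant=len(concordant),
            concordance=len(concordant) / n,
            discordant=discordant,
            moderate_only=moderate_only,
        )
    return reports


def concordance_tsv(reports: dict[str, ConcordanceReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("regulon_id\tn_members\tn_concordant\tconcordance\tmoderate_only\tdiscordant\tassessable\n")
        for rid in sorted(reports):
            r = reports[rid]
            fh.write(
                f"{rid}\t{r.n_members}\t{r.n_concordant}\t"
                f"{'' if not r.assessable else f'{r.concordance:.3f}'}\t"
                f"{','.join(r.moderate_only)}\t{','.join(r.discordant)}\t{r.assessable}\n"
            )
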