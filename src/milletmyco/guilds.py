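"""Trophic-guild annotation and aggregation.

OTUs are matched against a FUNGuild-style lookup at their most specific
assigned taxonomic rank; only assignments with confidence "Highly Probable"
or "Probable" are accepted.  Trophic-mode strings (hyphen-separated tokens
from pathotroph / saprotroph / symbiotroph) collapse into seven canonical
groups, whose per-sample relative abundances are correlated with soil
chemistry per site.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, SampleMetadata, TaxonomyTable, RANKS

log = logging.getLogger(__name__)

#: canonical seven trophic-mode groups (plus "Unassigned" for everything else)
TROPHIC_GROUPS = [
    "Pathotroph",
    "Saprotroph",
    "Symbiotroph",
    "Pat_Sap",
    "Pat_Sym",
    "Sap_Sym",
    "Pat_Sap_Sym",
]

UNASSIGNED = "Unassigned"

ACCEPTED_CONFIDENCE = {"highly probable", "probable"}

_TOKEN = {"pathotroph": "P", "saprotroph": "S", "symbiotroph": "Y"}

_COMBO = {
    frozenset("P"): "Pathotroph",
    frozenset("S"): "Saprotroph",
    frozenset("Y"): "Symbiotroph",
    frozenset("PS"): "Pat_Sap",
    frozenset("PY"): "Pat_Sym",
    frozenset("SY"): "Sap_Sym",
    frozenset("PSY"): "Pat_Sap_Sym",
}


def trophic_group(trophic_mode: str) -> str:
    """Collapse a hyphen-separated trophic-mode string into its canonical
    group label, independent of token order.  Unknown tokens yield
    "Unassigned" with a warning."""
    if trophic_mode is None or (isinstance(trophic_mode, float) and np.isnan(trophic_mode)):
        return UNASSIGNED
    tokens = [t.strip().lower() for t in str(trophic_mode).split("-") if t.strip()]
    if not tokens:
        return UNASSIGNED
    coded = set()
    for tok in tokens:
        if tok not in _TOKEN:
            log.warning("unknown trophic-mode token %r -> Unassigned", tok)
            return UNASSIGNED
        coded.add(_TOKEN[tok])
    return _COMBO[frozenset(coded)]


def packaged_guild_db() -> pd.DataFrame:
    """Load the packaged mini guild lookup: a synthetic stand-in for the
    full FUNGuild flat file, covering ~40 common root-fungal genera, built
    for tests and simulations."""
    from .io import read_guild_db

    with resources.as_file(
        resources.files("milletmyco").joinpath("data/guild_db_synthetic.tsv")
    ) as p:
        return read_guild_db(p)


def assign_guilds(taxonomy: TaxonomyTable, guild_db: pd.DataFrame) -> pd.DataFrame:
    """Annotate every OTU with guild/trophic information.

    Matching walks the lineage from species up to kingdom and takes the
    first (most specific) taxon present in the lookup, case-insensitively.
    Records whose confidence ranking is outside {Highly Probable, Probable}
    keep their raw fields but get trophic_group "Unassigned".

    Returns a DataFrame indexed by otu_id with columns matched_taxon,
    matched_rank, trophic_mode, guild, confidence, trophic_group.
    """
    lookup: dict[str, pd.Series] = {}
    for _, row in guild_db.iterrows():
        key = row["taxon"].lower()
        lookup.setdefault(key, row)

    records = []
    for otu_id in taxonomy.otu_ids:
        lineage = taxonomy.lineage(otu_id)
        rec = {
            "otu_id": otu_id,
            "matched_taxon": None,
            "matched_rank": None,
            "trophic_mode": None,
            "guild": None,
            "confidence": None,
            "trophic_group": UNASSIGNED,
        }
        for rank in reversed(RANKS):  # species first
            name = lineage.get(rank)
            if name is None:
                continue
            hit = lookup.get(name.lower())
            if hit is None:
                continue
            rec.update(
                matched_taxon=hit["taxon"],
                matched_rank=rank,
                trophic_mode=hit["trophicMode"],
                guild=hit["guild"],
                confidence=hit["confidenceRanking"],
            )
            if hit["confidenceRanking"].strip().lower() in ACCEPTED_CONFIDENCE:
                rec["trophic_group"] = trophic_group(hit["trophicMode"])
            break
        records.append(rec)
    return pd.DataFrame(records).set_index("otu_id")


def group_relative_abundance(
    table: CountTable,
    annotations: pd.DataFrame,
    level: str = "trophic_group",
    weight: str = "reads",
) -> pd.DataFrame:
    """Per-sample relative abundance of each guild or trophic group.

    Only assigned OTUs enter the denominator, so rows sum to 1 over the
    assigned groups.  ``weight="reads"`` uses read counts (the default);
    ``weight="otus"`` tallies presence of OTUs instead.

    Returns a samples x groups DataFrame; a sample with zero assigned
    counts becomes a row of NaN with a warning.
    """
    if level == "trophic_group":
        labels = annotations["trophic_group"]
    elif level == "guild":
        labels = annotations["guild"].where(
            annotations["trophic_group"] != UNASSIGNED, other=None
        )
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    if weight not in ("reads", "otus"):
        raise ValueError(f"unknown weight {weight!r}")

    counts = table.counts
    if weight == "otus":
        counts = (counts > 0).astype(int)
    labels = labels.reindex(counts.index)
    assigned = labels.notna() & (labels != UNASSIGNED)
    grouped = counts[assigned].groupby(labels[assigned].astype(str)).sum()  # groups x samples
    totals = grouped.sum(axis=0)
    empty = totals == 0
    if empty.any():
        log.warning(
            "%d sample(s) with zero assigned counts -> NaN rows: %s",
            int(empty.sum()),
            list(totals.index[empty]),
        )
    out = (grouped / totals.where(~empty)).T  # samples x groups
    out.index.name = "sample_id"
    return out


_STARS = [(0.001, "***"), (0.01, "**"), (0.05, "*")]


def _star(p: float) -> str:
    for cut, mark in _STARS:
        if p < cut:
            return mark
    return ""


def soil_trophic_correlation(
    group_abundance: pd.DataFrame,
    metadata: SampleMetadata,
    per_site: bool = True,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson correlation between soil variables and group relative
    abundances, within each site (or pooled with ``per_site=False``).

    Incomplete sample pairs are dropped pairwise (the number dropped is
    logged); cells with fewer than ``min_pairs`` complete pairs or a
    constant vector are NA.  p is two-sided from the t distribution with
    n-2 df; stars at 0.05/0.01/0.001 on the raw p, with a BH-adjusted
    column alongside.
    """
    meta = metadata.frame.loc[group_abundance.index]
    soil = metadata.soil().loc[group_abundance.index]
    site_groups = meta.groupby("site").groups if per_site else {"all": meta.index}

    rows = []
    for site, idx in site_groups.items():
        for var in soil.columns:
            x_all = soil.loc[idx, var]
            for grp in group_abundance.columns:
                y_all = group_abundance.loc[idx, grp]
                ok = x_all.notna() & y_all.notna()
                dropped = int((~ok).sum())
                if dropped:
                    log.info("site %s %s~%s: dropped %d incomplete pairs", site, var, grp, dropped)
                x, y = x_all[ok].to_numpy(float), y_all[ok].to_numpy(float)
                n = len(x)
                if n < min_pairs or np.ptp(x) == 0 or np.ptp(y) == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(x, y)
                rows.append(
                    {"site": site, "soil_var": var, "trophic_group": grp,
                     "n": n, "r": r, "p": p}
                )
    out = pd.DataFrame(rows)
    out["stars"] = out["p"].map(lambda p: "" if np.isnan(p) else _star(p))
    from .ordination import bh_fdr

    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out
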