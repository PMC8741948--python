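"""Rarefaction and per-sample alpha diversity.

Rarefaction subsamples each library without replacement (multivariate
hypergeometric) down to a common depth, matching vegan-style "rarefy"
semantics; samples below the target depth are dropped with a warning.
Shannon is reported in nats, Simpson as the Gini-Simpson complement
1 - sum(p^2) (the raw dominance D is exported too).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CountTable, SampleMetadata

log = logging.getLogger(__name__)


def rarefy(table: CountTable, depth: int, seed) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without
    replacement.  Samples whose library is below ``depth`` are dropped
    (logged); an error is raised if none remain.  Deterministic given
    ``seed`` (int or Generator)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = table.library_sizes()
    keep = sizes[sizes >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        log.warning("rarefy: dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    if len(keep) == 0:
        raise ValueError(f"all samples have fewer than {depth} reads")
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        out[s] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    return CountTable(pd.DataFrame(out, index=table.counts.index))


def _props(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    return c[c > 0] / total


def richness(counts) -> int:
    """Observed OTUs: #{i : count_i > 0}."""
    return int(len(_props(counts)))


def shannon(counts) -> float:
    """Shannon entropy -sum(p ln p) in nats over nonzero proportions."""
    p = _props(counts)
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum(p^2)."""
    p = _props(counts)
    return float(1.0 - (p * p).sum())


def simpson_dominance(counts) -> float:
    """Raw Simpson dominance D = sum(p^2)."""
    return 1.0 - simpson(counts)


def alpha_table(table: CountTable, metadata: SampleMetadata) -> pd.DataFrame:
    """One row per sample: richness, shannon, simpson (Gini-Simpson),
    simpson_D, joined with site / plant_type / plot.  This is exactly the
    tidy table a mixed-model refit of the diversity indices would consume."""
    rows = []
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        rows.append(
            {
                "sample_id": s,
                "richness": richness(col),
                "shannon": shannon(col),
                "simpson": simpson(col),
                "simpson_D": simpson_dominance(col),
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    meta = metadata.frame.loc[out.index, ["site", "plant_type", "plot"]]
    return out.join(meta)


def expected_rarefied_richness(counts, depth: int) -> float:
    """Closed-form expectation of richness after rarefying one sample to
    ``depth``: sum_i (1 - C(N - N_i, d) / C(N, d)), the hypergeometric
    probability that OTU i survives the subsample."""
    from scipy.special import gammaln

    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    N = int(c.sum())
    if depth > N:
        raise ValueError("depth exceeds library size")

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    miss = np.where(N - c >= depth, np.exp(logC(N - c, depth) - logC(N, depth)), 0.0)
    return float((1.0 - miss).sum())
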