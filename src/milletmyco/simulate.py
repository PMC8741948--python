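"""Ground-truthed OTU-table simulator.

Emulates a 60-sample root-mycobiome survey: 3 sites with a 2/3/1 plot
split, 2 plant types (cultivated / wild), 5 replicates per plot x plant
type, uneven library sizes, long-tail OTU abundances, correlated OTU
blocks and hub-and-spoke correlation structure, plant-type differences in
trophic composition, and soil covariates correlated with trophic-group
abundances.  Counts come from a Gaussian copula with negative-binomial
marginals followed by multinomial subsampling to the drawn library size,
so planted rank correlations survive into the observed table.

Every planted feature is reported back in a :class:`GroundTruth` object
for parameter-recovery tests.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, SampleMetadata, TaxonomyTable, SOIL_VARS
from .guilds import TROPHIC_GROUPS, UNASSIGNED, ACCEPTED_CONFIDENCE, trophic_group, packaged_guild_db

log = logging.getLogger(__name__)


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


# default trophic-composition targets per plant type: pathotroph-skewed in
# cultivated, saprotroph-skewed in wild, minor groups shared
DEFAULT_GUILD_MIX = {
    "cultivated": {
        "Pathotroph": 0.42, "Saprotroph": 0.24, "Symbiotroph": 0.04,
        "Pat_Sap": 0.03, "Pat_Sym": 0.02, "Sap_Sym": 0.14, "Pat_Sap_Sym": 0.11,
    },
    "wild": {
        "Pathotroph": 0.34, "Saprotroph": 0.32, "Symbiotroph": 0.04,
        "Pat_Sap": 0.03, "Pat_Sym": 0.02, "Sap_Sym": 0.14, "Pat_Sap_Sym": 0.11,
    },
}

DEFAULT_BLOCKS = [(10, 0.8, 1), (8, 0.7, 1), (6, 0.6, -1)]
DEFAULT_HUBS = [(30, 12, 0.85)]
DEFAULT_SOIL_CORR = [
    ("total_P", "Pathotroph", 0.6),
    ("pH_H2O", "Sap_Sym", -0.5),
    ("assimilable_P", "Saprotroph", 0.5),
]

# (site mean, between-site spread, within-site sd) per soil variable,
# loosely matching sandy West-African topsoil: pH ~6.2, C ~0.45 %,
# N ~0.035 %, total P ~70 mg/kg
SOIL_BASELINES = {
    "pH_H2O": (6.2, 0.4, 0.25),
    "total_C": (0.45, 0.10, 0.08),
    "total_N": (0.035, 0.008, 0.006),
    "C_N": (12.0, 1.5, 1.2),
    "total_P": (70.0, 15.0, 12.0),
    "assimilable_P": (15.0, 5.0, 4.0),
    "NO3": (8.0, 2.0, 2.0),
    "NH4": (5.0, 1.5, 1.2),
}


@dataclass
class SimConfig:
    """Design constants and planted structure for one simulated survey."""

    n_sites: int = 3
    n_plant_types: int = 2  # fixed by the design
    plots_per_site: tuple = (2, 3, 1)  # any partition; an int means equal
    n_reps: int = 5
    n_otus: int = 600
    depth_range: tuple = (25_556, 154_517)
    block_spec: list = field(default_factory=lambda: list(DEFAULT_BLOCKS))
    hub_spec: list = field(default_factory=lambda: list(DEFAULT_HUBS))
    site_effect_sd: float = 0.5
    plant_effect_sd: float = 0.2
    plant_richness_effect: float = 0.0  # log-fold depletion of rare OTUs in wild
    guild_mix: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GUILD_MIX.items()})
    soil_corr_spec: list = field(default_factory=lambda: list(DEFAULT_SOIL_CORR))
    nb_dispersion: float = 2.0
    abundance_sigma: float = 1.0  # lognormal shape of the long-tail mean profile
    planted_rank_start: float = 0.1  # abundance quantile where planted OTUs begin
    assigned_fraction: float = 0.75  # OTUs resolvable in the guild lookup
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.plots_per_site, int):
            self.plots_per_site = tuple([self.plots_per_site] * self.n_sites)
        else:
            self.plots_per_site = tuple(self.plots_per_site)

    def validate(self) -> None:
        if self.n_sites < 1:
            raise SimConfigError("n_sites must be >= 1")
        if self.n_plant_types != 2:
            raise SimConfigError("n_plant_types is fixed at 2 (cultivated, wild)")
        if len(self.plots_per_site) != self.n_sites or any(p < 1 for p in self.plots_per_site):
            raise SimConfigError("plots_per_site must give >= 1 plot for each site")
        if self.n_reps < 1:
            raise SimConfigError("n_reps must be >= 1")
        if self.n_otus < 2:
            raise SimConfigError("n_otus must be >= 2")
        lo, hi = self.depth_range
        if not (1 <= lo <= hi):
            raise SimConfigError("depth_range must satisfy 1 <= low <= high")
        used = set()
        for k, (size, rho, sign) in enumerate(self.block_spec):
            if size < 2:
                raise SimConfigError(f"block_spec[{k}]: block size must be >= 2")
            if not abs(rho) < 1:
                raise SimConfigError(f"block_spec[{k}]: |rho| must be < 1")
            if sign not in (-1, 1):
                raise SimConfigError(f"block_spec[{k}]: sign must be +1 or -1")
        blocks_total = sum(b[0] for b in self.block_spec)
        if self.n_otus < blocks_total:
            raise SimConfigError("n_otus must be >= total block size in block_spec")
        used.update(range(blocks_total))
        for k, (hub, n_partners, rho) in enumerate(self.hub_spec):
            if not abs(rho) < 1:
                raise SimConfigError(f"hub_spec[{k}]: |rho| must be < 1")
            span = set(range(hub, hub + n_partners + 1))
            if max(span, default=-1) >= self.n_otus or min(span, default=0) < 0:
                raise SimConfigError(f"hub_spec[{k}]: hub/partner indices exceed n_otus")
            if span & used:
                raise SimConfigError(f"hub_spec[{k}]: overlaps another correlated block")
            used.update(span)
        for pt, mix in self.guild_mix.items():
            if set(mix) != set(TROPHIC_GROUPS):
                raise SimConfigError(f"guild_mix[{pt}] must cover the 7 trophic groups")
            vals = np.array(list(mix.values()), float)
            if (vals < 0).any() or (vals > 1).any() or abs(vals.sum() - 1) > 1e-9:
                raise SimConfigError(f"guild_mix[{pt}] proportions must be in [0,1] and sum to 1")
        seen_vars = set()
        for var, grp, r in self.soil_corr_spec:
            if var not in SOIL_VARS:
                raise SimConfigError(f"soil_corr_spec: unknown soil variable {var!r}")
            if grp not in TROPHIC_GROUPS:
                raise SimConfigError(f"soil_corr_spec: unknown trophic group {grp!r}")
            if not abs(r) < 1:
                raise SimConfigError("soil_corr_spec: |target r| must be < 1")
            if var in seen_vars:
                raise SimConfigError(f"soil_corr_spec: duplicate soil variable {var!r}")
            seen_vars.add(var)
        if not 0 < self.nb_dispersion:
            raise SimConfigError("nb_dispersion must be > 0")
        if not 0 <= self.assigned_fraction <= 1:
            raise SimConfigError("assigned_fraction must be in [0,1]")
        if not 0 <= self.planted_rank_start < 1:
            raise SimConfigError("planted_rank_start must be in [0,1)")
        n_planted = len(self.planted_indices())
        if int(self.planted_rank_start * self.n_otus) + n_planted > self.n_otus:
            raise SimConfigError("planted_rank_start leaves no room for the planted OTUs")

    def planted_indices(self) -> list[int]:
        """All OTU indices carrying planted correlation structure."""
        idx = set(range(sum(b[0] for b in self.block_spec)))
        for hub, n_partners, _ in self.hub_spec:
            idx.update(range(hub, hub + n_partners + 1))
        return sorted(idx)

    @property
    def n_samples(self) -> int:
        return 2 * self.n_reps * sum(self.plots_per_site)


@dataclass
class GroundTruth:
    """Everything that was planted, for recovery tests."""

    block_membership: dict            # otu_id -> block index
    planted_hubs: list                # otu ids
    planted_pairwise_rho: dict        # (otu_id, otu_id) sorted tuple -> signed rho
    effect_table: pd.DataFrame        # per-OTU log-fold site/plant effects
    soil_links: list                  # dicts: soil_var, trophic_group, site, target_r, realized_r

    def to_json(self, path) -> None:
        eff = self.effect_table.round(5)
        payload = {
            "block_membership": self.block_membership,
            "planted_hubs": self.planted_hubs,
            "planted_pairwise_rho": {
                f"{a}|{b}": round(r, 5) for (a, b), r in self.planted_pairwise_rho.items()
            },
            "effect_table": eff.reset_index().to_dict(orient="list"),
            "soil_links": self.soil_links,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        eff = pd.DataFrame(payload["effect_table"]).set_index("otu_id")
        return cls(
            block_membership=payload["block_membership"],
            planted_hubs=payload["planted_hubs"],
            planted_pairwise_rho={
                tuple(k.split("|")): r for k, r in payload["planted_pairwise_rho"].items()
            },
            effect_table=eff,
            soil_links=payload["soil_links"],
        )


# ---------------------------------------------------------------------------
# copula count machinery
# ---------------------------------------------------------------------------


def _child_rng(seed: int, stage: int) -> np.random.Generator:
    """Counter-based child stream: one global seed, one fixed index per stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _psd_cholesky(corr: np.ndarray) -> np.ndarray:
    """Cholesky factor; non-PSD input is projected to the nearest PSD
    correlation matrix (eigenvalue clipping + diagonal renormalization)
    with a logged warning."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        log.warning("correlation matrix not PSD; projecting to nearest PSD")
        w, v = np.linalg.eigh((corr + corr.T) / 2)
        w = np.clip(w, 1e-10, None)
        fixed = (v * w) @ v.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        np.fill_diagonal(fixed, 1.0)
        return np.linalg.cholesky(fixed + 1e-10 * np.eye(len(fixed)))


def _nb_quantile(u: np.ndarray, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial quantile with mean/dispersion parameterization
    (var = m + m^2/k); k = inf degenerates to Poisson."""
    out = np.zeros_like(mean)
    pos = mean > 0
    if not pos.any():
        return out
    if np.isinf(dispersion):
        out[pos] = stats.poisson.ppf(u[pos], mean[pos])
    else:
        k = dispersion
        p = k / (k + mean[pos])
        out[pos] = stats.nbinom.ppf(u[pos], k, p)
    return out


def correlated_counts(
    marginal_means: np.ndarray,
    dispersion: float,
    corr: np.ndarray,
    depth: int,
    seed,
) -> np.ndarray:
    """Draw one sample's OTU count vector summing exactly to ``depth``.

    Gaussian copula: z ~ MVN(0, corr), u = Phi(z), counts via the
    negative-binomial quantile per OTU, then multinomial subsampling of
    the raw vector down to ``depth`` reads.  ``seed`` may be an int or a
    Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.asarray(marginal_means, float)
    L = _psd_cholesky(np.asarray(corr, float)) if corr is not None else None
    return _draw_sample(rng, means, dispersion, L, depth)


def _draw_sample(rng, means, dispersion, chol, depth) -> np.ndarray:
    z = rng.standard_normal(len(means))
    if chol is not None:
        z = chol @ z
    u = stats.norm.cdf(z)
    raw = _nb_quantile(u, means, dispersion)
    total = raw.sum()
    probs = raw / total if total > 0 else means / means.sum()
    return rng.multinomial(depth, probs)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

_PHYLUM = {
    "Coprinopsis": "Basidiomycota", "Ustilago": "Basidiomycota",
    "Serendipita": "Basidiomycota", "Rhizoctonia": "Basidiomycota",
    "Moesziomyces": "Basidiomycota",
    "Glomus": "Glomeromycota", "Rhizophagus": "Glomeromycota",
    "Funneliformis": "Glomeromycota", "Mortierella": "Mortierellomycota",
}
_FAMILY = {
    "Fusarium": "Nectriaceae", "Curvularia": "Pleosporaceae",
    "Bipolaris": "Pleosporaceae", "Cochliobolus": "Pleosporaceae",
    "Alternaria": "Pleosporaceae", "Stemphylium": "Pleosporaceae",
    "Pyrenophora": "Pleosporaceae", "Penicillium": "Aspergillaceae",
    "Talaromyces": "Trichocomaceae", "Chaetomium": "Chaetomiaceae",
    "Cladosporium": "Cladosporiaceae", "Exophiala": "Herpotrichiellaceae",
}
# genera kept out of the lookup on purpose (unresolvable OTUs)
_UNKNOWN_GENERA = ["Sordaria", "Myrothecium", "Ganoderma", "Westerdykella"]


def _build_corr(config: SimConfig):
    """Block + hub correlation matrix and the planted pairwise map."""
    n = config.n_otus
    corr = np.eye(n)
    membership: dict[int, int] = {}
    planted: dict[tuple[int, int], float] = {}
    pos = 0
    for b, (size, rho, sign) in enumerate(config.block_spec):
        idx = np.arange(pos, pos + size)
        # one-factor construction: loadings +-sqrt(rho) give exact +-rho
        loadings = np.full(size, np.sqrt(abs(rho)))
        if sign < 0:
            loadings[1::2] *= -1
        sub = np.outer(loadings, loadings)
        np.fill_diagonal(sub, 1.0)
        corr[np.ix_(idx, idx)] = sub
        for i in range(size):
            membership[int(idx[i])] = b
            for j in range(i + 1, size):
                planted[(int(idx[i]), int(idx[j]))] = float(sub[i, j])
        pos += size
    hubs = []
    for hub, n_partners, rho in config.hub_spec:
        partners = np.arange(hub + 1, hub + 1 + n_partners)
        corr[hub, partners] = corr[partners, hub] = rho
        sub = np.full((n_partners, n_partners), rho * rho)
        np.fill_diagonal(sub, 1.0)
        corr[np.ix_(partners, partners)] = sub
        hubs.append(int(hub))
        for p in partners:
            planted[(int(hub), int(p))] = float(rho)
    return corr, membership, hubs, planted


def _sample_frame(config: SimConfig) -> pd.DataFrame:
    rows = []
    plot_no = 0
    for s in range(config.n_sites):
        site = f"S{s + 1}"
        for _ in range(config.plots_per_site[s]):
            plot_no += 1
            plot = f"P{plot_no}"
            for pt in ("cultivated", "wild"):
                for r in range(1, config.n_reps + 1):
                    rows.append(
                        {"sample_id": f"{site}.{plot}.{pt[:4]}.r{r}",
                         "site": site, "plant_type": pt, "plot": plot}
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_dataset(config: SimConfig):
    """Simulate one complete survey.

    Returns ``(CountTable, SampleMetadata, TaxonomyTable, annotations,
    GroundTruth)`` where ``annotations`` is the guild table produced by
    running the packaged lookup over the generated taxonomy.  Identical
    config + seed reproduces identical output.
    """
    config.validate()
    rng_tax = _child_rng(config.seed, 0)
    rng_eff = _child_rng(config.seed, 1)
    rng_counts = _child_rng(config.seed, 2)
    rng_soil = _child_rng(config.seed, 3)

    n = config.n_otus
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n)]
    frame = _sample_frame(config)

    # long-tail mean profile; planted OTUs take abundance ranks starting at
    # the planted_rank_start quantile — prevalent, core-taxon-level
    # abundances rather than the dominant few, so closure noise from the
    # top taxa does not swamp the planted rank correlations
    profile = np.sort(rng_tax.lognormal(0.0, config.abundance_sigma, n))[::-1]
    profile /= profile.sum()
    planted_idx = config.planted_indices()
    start = int(config.planted_rank_start * n)
    planted_ranks = list(range(start, start + len(planted_idx)))
    other_idx = [i for i in range(n) if i not in set(planted_idx)]
    other_ranks = [r for r in range(n) if r not in set(planted_ranks)]
    base = np.empty(n)
    base[planted_idx] = profile[planted_ranks]
    base[other_idx] = profile[other_ranks]

    # trophic-group and genus assignment
    db = packaged_guild_db()
    accepted = db[db["confidenceRanking"].str.lower().isin(ACCEPTED_CONFIDENCE)]
    genera_by_group: dict[str, list[str]] = {}
    for _, row in accepted[accepted["taxonomicLevel"] == "genus"].iterrows():
        genera_by_group.setdefault(trophic_group(row["trophicMode"]), []).append(row["taxon"])
    mean_mix = {
        g: np.mean([config.guild_mix[pt][g] for pt in config.guild_mix])
        for g in TROPHIC_GROUPS
    }
    probs = np.array([mean_mix[g] for g in TROPHIC_GROUPS])
    probs /= probs.sum()
    groups = np.full(n, UNASSIGNED, dtype=object)
    genera = np.empty(n, dtype=object)
    for i in range(n):
        if rng_tax.random() < config.assigned_fraction:
            g = TROPHIC_GROUPS[rng_tax.choice(len(TROPHIC_GROUPS), p=probs)]
            groups[i] = g
            genera[i] = genera_by_group[g][rng_tax.integers(len(genera_by_group[g]))]
        else:
            genera[i] = (
                _UNKNOWN_GENERA[rng_tax.integers(len(_UNKNOWN_GENERA))]
                if rng_tax.random() < 0.5
                else None
            )
    taxonomy = TaxonomyTable(
        pd.DataFrame(
            {
                "kingdom": "Fungi",
                "phylum": [_PHYLUM.get(g, "Ascomycota") if g else None for g in genera],
                "family": [_FAMILY.get(g) if g else None for g in genera],
                "genus": [g if g else None for g in genera],
            },
            index=pd.Index(otu_ids, name="otu_id"),
        )
    )

    # log-scale effects
    sites = [f"S{s + 1}" for s in range(config.n_sites)]
    site_eff = rng_eff.normal(0.0, config.site_effect_sd, (n, config.n_sites))
    plant_delta = rng_eff.normal(0.0, config.plant_effect_sd, n)
    rich_mask = rng_eff.random(n) < 0.4
    effect_table = pd.DataFrame(
        site_eff, index=pd.Index(otu_ids, name="otu_id"), columns=[f"site_{s}" for s in sites]
    )
    effect_table["plant_delta"] = plant_delta  # +d/2 cultivated, -d/2 wild
    effect_table["wild_richness_depletion"] = np.where(
        rich_mask, config.plant_richness_effect, 0.0
    )

    # trophic tilt so realized composition tracks guild_mix per plant type
    tilt = {}
    for pt in ("cultivated", "wild"):
        base_share = {
            g: base[groups == g].sum() for g in TROPHIC_GROUPS if (groups == g).any()
        }
        f = np.ones(n)
        for g, share in base_share.items():
            if share > 0:
                f[groups == g] = config.guild_mix[pt][g] / share * sum(base_share.values())
        tilt[pt] = f

    corr, membership, hub_idx, planted = _build_corr(config)
    chol = _psd_cholesky(corr) if (config.block_spec or config.hub_spec) else None

    lo, hi = config.depth_range
    depths = np.rint(np.exp(rng_counts.uniform(np.log(lo), np.log(hi), len(frame)))).astype(int)
    depths = np.clip(depths, lo, hi)

    counts = np.zeros((n, len(frame)), dtype=np.int64)
    for j, (sid, row) in enumerate(frame.iterrows()):
        s = sites.index(row["site"])
        sign = 0.5 if row["plant_type"] == "cultivated" else -0.5
        logw = site_eff[:, s] + sign * plant_delta
        if row["plant_type"] == "wild":
            logw = logw - effect_table["wild_richness_depletion"].to_numpy()
        w = base * np.exp(logw) * tilt[row["plant_type"]]
        p = w / w.sum()
        counts[:, j] = _draw_sample(rng_counts, p * depths[j], config.nb_dispersion, chol, depths[j])

    table = CountTable(pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"), columns=frame.index))

    # trophic relative abundances (assigned only) drive the soil covariates
    assigned = groups != UNASSIGNED
    trophic_ab = pd.DataFrame(index=frame.index, columns=TROPHIC_GROUPS, dtype=float)
    tot = counts[assigned].sum(axis=0)
    for g in TROPHIC_GROUPS:
        sel = groups == g
        trophic_ab[g] = counts[sel].sum(axis=0) / np.where(tot > 0, tot, 1)

    soil, soil_links = generate_soil(frame, trophic_ab, config.soil_corr_spec, rng_soil)
    metadata = SampleMetadata(frame.join(soil))

    from .guilds import assign_guilds

    annotations = assign_guilds(taxonomy, db)

    truth = GroundTruth(
        block_membership={otu_ids[i]: b for i, b in membership.items()},
        planted_hubs=[otu_ids[i] for i in hub_idx],
        planted_pairwise_rho={
            (otu_ids[i], otu_ids[j]): r for (i, j), r in planted.items()
        },
        effect_table=effect_table,
        soil_links=soil_links,
    )
    return table, metadata, taxonomy, annotations, truth


def generate_soil(
    frame: pd.DataFrame,
    trophic_abundance: pd.DataFrame,
    soil_corr_spec,
    seed,
):
    """Soil-chemistry vectors with planted within-site Pearson correlations.

    For each (soil variable, trophic group, target r) entry the variable is
    built per site as ``r * z + sqrt(1 - r^2) * e`` with ``z`` the
    standardized group abundance and ``e`` noise orthogonalized against
    ``z``, so the within-site sample correlation hits the target exactly
    (up to degenerate abundance vectors).  Unlisted variables are
    independent normals around site-specific means.

    Returns ``(soil DataFrame, realized links)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec_by_var = {}
    for var, grp, r in soil_corr_spec:
        if var not in SOIL_VARS:
            raise SimConfigError(f"generate_soil: unknown soil variable {var!r}")
        if grp not in trophic_abundance.columns:
            raise SimConfigError(f"generate_soil: unknown trophic group {grp!r}")
        spec_by_var[var] = (grp, float(r))

    if not frame.index.equals(trophic_abundance.index):
        raise SimConfigError("generate_soil: trophic abundance not aligned to samples")

    soil = pd.DataFrame(index=frame.index, columns=SOIL_VARS, dtype=float)
    links = []
    site_of = frame["site"]
    for var in SOIL_VARS:
        base, spread, sd = SOIL_BASELINES[var]
        for site in site_of.unique():
            idx = site_of.index[site_of == site]
            m = len(idx)
            site_mean = base + rng.normal(0.0, spread)
            e = rng.standard_normal(m)
            if var in spec_by_var:
                grp, r = spec_by_var[var]
                z = trophic_abundance.loc[idx, grp].to_numpy(float)
                if np.ptp(z) == 0 or m < 3:
                    x = e  # degenerate: cannot plant a correlation
                else:
                    z = (z - z.mean()) / z.std()
                    e = e - z * (e @ z) / (z @ z)
                    e = e - e.mean()
                    e = e / e.std() if e.std() > 0 else e
                    x = r * z + np.sqrt(1 - r * r) * e
                vals = site_mean + sd * x
                soil.loc[idx, var] = vals
                realized = (
                    float(np.corrcoef(vals, trophic_abundance.loc[idx, grp])[0, 1])
                    if np.ptp(z) > 0 and m >= 3
                    else float("nan")
                )
                links.append(
                    {"soil_var": var, "trophic_group": grp, "site": str(site),
                     "target_r": r, "realized_r": realized}
                )
            else:
                soil.loc[idx, var] = site_mean + sd * e
    return soil, links
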