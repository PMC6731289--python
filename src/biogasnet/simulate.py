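"""Synthetic metaproteome generator with known ground truth.

Emulates the study design the pipeline targets: a panel of biogas plants
(default 16) sampled with 5 biological replicates each, yielding a
protein-group relative-abundance table (a few hundred features), a feature
annotation (species / family / KO), and per-plant process metadata.

The generative model, in order:

1. every non-methanogen species gets a log-normal base abundance and an
   independent per-sample log-normal fluctuation;
2. planted associations are realized through shared latent factors: the
   planted edges are grouped into connected components, every species in a
   component loads on the component's per-sample factor with weight
   ``+-sqrt(rho)`` (sign chosen so each planted edge's co-presence/exclusion
   sign equals the product of its endpoint signs), so each planted pair's
   latent log-abundances correlate at about ``+-rho``;
3. metadata-linked species additionally track a per-plant latent that also
   drives the linked metadata variable monotonically;
4. four methanogen carrier species hold the methanogenesis KO mass: per
   sample the acetoclastic-unique : hydrogenotrophic-unique abundance ratio
   is set exactly to the plant's ``F_true`` before noise;
5. species mass is split over a species-specific number of protein groups
   with fixed Dirichlet weights;
6. multiplicative log-normal replicate noise, then random dropout (zeroing a
   feature within a replicate), then compositional closure to 100% per sample.

Because closure is applied last, planted correlations are specified on the
latent (pre-closure) scale; the returned ground truth therefore also reports
the *realized* post-closure rank correlation of every planted pair, which is
what recovery tests should compare against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import SAMPLE_INDEX_NAMES, normalize_relative
from .pathways import KoPathwaySets, classify_F

METADATA_VARIABLES = (
    "temperature", "ph", "vfa", "cn_ratio",
    "maize_silage", "grass_silage", "cow_manure",
    "dry_manure", "corn", "food_residues",
)
_FRACTION_VARIABLES = METADATA_VARIABLES[4:]


@dataclass(frozen=True)
class PlantedEdge:
    """A pairwise association written into the data: sign +1 co-presence, -1 exclusion."""

    a: str
    b: str
    sign: int
    rho: float = 0.9

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if self.a == self.b:
            raise ValueError("planted edge must join two distinct species")

    @property
    def pair(self) -> tuple:
        return tuple(sorted((self.a, self.b)))


@dataclass(frozen=True)
class MetadataLink:
    """A planted monotone link between a species and a metadata variable."""

    species: str
    variable: str
    direction: int = 1

    def __post_init__(self):
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.variable not in METADATA_VARIABLES:
            raise ValueError(f"unknown metadata variable {self.variable!r}")


def species_id(i: int) -> str:
    """Short species key, 'S' + 4 digits."""
    return f"S{i:04d}"


def _planted_components(edges) -> list[tuple[dict, float]]:
    """Group planted edges into signed factor components.

    Each connected component of the planted-edge graph must be *complete*
    (every within-component pair planted) and *sign-consistent* (edge sign =
    product of endpoint signs for some +-1 assignment) with a single rho, so
    that one shared latent factor realizes exactly the planted structure and
    nothing else.  Returns ``[(sign_of_species, rho), ...]``.
    """
    adj: dict[str, list] = {}
    pair_map: dict[tuple, "PlantedEdge"] = {}
    for e in edges:
        if e.pair in pair_map:
            raise ValueError(f"duplicate planted edge {e.pair}")
        pair_map[e.pair] = e
        adj.setdefault(e.a, []).append((e.b, e.sign))
        adj.setdefault(e.b, []).append((e.a, e.sign))
    components = []
    seen: set = set()
    for root in sorted(adj):
        if root in seen:
            continue
        sign = {root: 1}
        stack = [root]
        seen.add(root)
        while stack:
            u = stack.pop()
            for v, s in adj[u]:
                want = sign[u] * s
                if v in sign:
                    if sign[v] != want:
                        raise ValueError(
                            "planted edge signs are inconsistent around species "
                            f"{v!r}: not realizable with one factor per group"
                        )
                else:
                    sign[v] = want
                    seen.add(v)
                    stack.append(v)
        members = sorted(sign)
        rhos = set()
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                e = pair_map.get((members[i], members[j]))
                if e is None:
                    raise ValueError(
                        "planted edges must form complete signed groups: pair "
                        f"({members[i]}, {members[j]}) is connected through other "
                        "edges but not itself planted"
                    )
                rhos.add(e.rho)
        if len(rhos) > 1:
            raise ValueError("all edges of one planted group must share the same rho")
        components.append((sign, rhos.pop()))
    return components


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults emulate the 16-plant x 5-replicate design.

    ``f_true`` maps plant id to the true acetoclastic:hydrogenotrophic unique-KO
    abundance ratio; the default splits the panel 8 hydrogenotrophic (F = 0.1),
    5 acetoclastic (F = 4.0) and 3 mixed (F = 1.0), mirroring the published
    panel composition.  ``noise_sd`` is the sd of the multiplicative log-normal
    replicate noise (default 0.3); ``dropout_prob`` zeroes a feature within a
    replicate (default 0.05).
    """

    n_plants: int = 16
    n_replicates: int = 5
    n_species: int = 40
    groups_per_species: tuple = (2, 6)
    f_true: dict | None = None
    methanogen_fraction: float = 0.35
    unique_ko_fraction: float = 0.4
    planted_edges: tuple = ()
    metadata_links: tuple = ()
    dropout_prob: float = 0.05
    noise_sd: float = 0.3
    base_log_sd: float = 1.0
    sample_log_sd: float = 0.7
    metadata_link_scale: float = 1.0
    seed: int = 0

    N_METHANOGENS = 4  # two acetoclastic + two hydrogenotrophic carrier species

    def plants(self) -> list:
        return [f"BP{i:02d}" for i in range(1, self.n_plants + 1)]

    def free_species(self) -> list:
        return [species_id(i) for i in range(self.N_METHANOGENS + 1, self.n_species + 1)]

    def resolved_f_true(self) -> dict:
        if self.f_true is not None:
            out = dict(self.f_true)
            if set(out) != set(self.plants()):
                raise ValueError("f_true must provide a value for every plant")
            if any(not f > 0 for f in out.values()):
                raise ValueError("F_true must be positive for every plant")
            return out
        return {
            p: [0.1, 4.0, 1.0][0 if i % 16 < 8 else (1 if i % 16 < 13 else 2)]
            for i, p in enumerate(self.plants())
        }

    def validate(self) -> list[tuple[dict, float]]:
        if self.n_plants < 1 or self.n_replicates < 1:
            raise ValueError("need at least one plant and one replicate")
        if self.n_species < self.N_METHANOGENS + 2:
            raise ValueError("n_species too small for the methanogen carriers")
        lo, hi = self.groups_per_species
        if not 1 <= lo <= hi:
            raise ValueError("invalid groups_per_species range")
        free = set(self.free_species())
        n_free_pairs = len(free) * (len(free) - 1) // 2
        if len(self.planted_edges) > n_free_pairs:
            raise ValueError("planted edges exceed the number of available species pairs")
        for e in self.planted_edges:
            for sp in (e.a, e.b):
                if sp not in free:
                    raise ValueError(
                        f"planted edge species {sp!r} is not a free (non-methanogen) species"
                    )
        components = _planted_components(self.planted_edges)
        linked_vars = [link.variable for link in self.metadata_links]
        if len(linked_vars) != len(set(linked_vars)):
            raise ValueError("each metadata variable may carry at most one planted link")
        for link in self.metadata_links:
            if link.species not in free:
                raise ValueError(f"metadata link species {link.species!r} is not free")
        self.resolved_f_true()
        return components


@dataclass
class GroundTruth:
    """What the generator wrote into the data.

    ``carrier_species`` lists the methanogen carrier species.  Their shared
    pathway-activity fluctuation makes the carrier block co-vary by design;
    pairs touching a carrier are therefore *known* structure rather than
    background, and recovery metrics exclude them from the planted-edge
    universe.
    """

    f_true: dict
    label_true: dict
    planted_edges: tuple
    metadata_links: tuple
    carrier_species: tuple = ()
    realized_rho: dict = field(default_factory=dict)


def _species_names(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i in range(1, cfg.n_species + 1):
        sid = species_id(i)
        if i <= 2:
            rows.append((sid, f"Methanosarcina sim{i}", "Methanosarcinaceae"))
        elif i <= cfg.N_METHANOGENS:
            rows.append((sid, f"Methanoculleus sim{i}", "Methanomicrobiaceae"))
        else:
            fam = ("Clostridiaceae", "Peptococcaceae", "Thermotogaceae",
                   "Pseudomonadaceae", "Lachnospiraceae")[i % 5]
            rows.append((sid, f"Bacterium sim{i}", fam))
    return pd.DataFrame(rows, columns=["species_id", "species_name", "family"])


def _metadata_table(cfg: SimulationConfig, u_plant: dict, rng) -> pd.DataFrame:
    """Per-plant process metadata; linked variables are monotone in their latent."""
    plants = cfg.plants()
    n = len(plants)
    base = {
        "temperature": 40 + 4 * rng.standard_normal(n),
        "ph": 7.5 + 0.25 * rng.standard_normal(n),
        "vfa": np.exp(5.5 + 0.8 * rng.standard_normal(n)),
        "cn_ratio": 22 + 4 * rng.standard_normal(n),
    }
    for var in _FRACTION_VARIABLES:
        base[var] = rng.uniform(0, 1, n)
    meta = pd.DataFrame(base, index=pd.Index(plants, name="plant_id"))
    scale = {"temperature": 4.0, "ph": 0.25, "vfa": 150.0, "cn_ratio": 4.0}
    for var, u in u_plant.items():
        if var in _FRACTION_VARIABLES:
            meta[var] = 1.0 / (1.0 + np.exp(-u))      # monotone, stays in (0, 1)
        else:
            meta[var] = meta[var].mean() + scale[var] * u
    for var in _FRACTION_VARIABLES:
        meta[var] = meta[var].clip(0, 1)
    meta["vfa"] = meta["vfa"].clip(lower=1.0)
    return meta


def simulate_dataset(config: SimulationConfig):
    """Generate ``(abundance, annotation, metadata, truth)`` for a config.

    Deterministic given ``config.seed``; see the module docstring for the
    generative model.  Raises ``ValueError`` for infeasible configs.
    """
    cfg = config
    components = cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    plants = cfg.plants()
    f_true = cfg.resolved_f_true()
    samples = [(p, r) for p in plants for r in range(1, cfg.n_replicates + 1)]
    n_samp = len(samples)
    plant_of = np.array([p for p, _ in samples])
    names = _species_names(cfg)
    free_species = cfg.free_species()

    # latent per-plant drivers for metadata links
    u_plant = {
        link.variable: rng.standard_normal(len(plants)) for link in cfg.metadata_links
    }
    plant_pos = {p: i for i, p in enumerate(plants)}

    # --- latent species log-abundances -------------------------------------
    loading: dict[str, tuple[int, float, int]] = {}  # species -> (sign, rho, comp idx)
    comp_order = sorted(range(len(components)), key=lambda k: min(components[k][0]))
    factors = {}
    for rank, k in enumerate(comp_order):
        sign_map, rho = components[k]
        factors[rank] = rng.standard_normal(n_samp)
        for sp, sgn in sign_map.items():
            loading[sp] = (sgn, rho, rank)
    link_of = {link.species: link for link in cfg.metadata_links}

    latent = {}
    for sp in free_species:
        eps = rng.standard_normal(n_samp)
        z = rng.normal(0.0, cfg.base_log_sd) + np.zeros(n_samp)
        if sp in loading:
            sgn, rho, k = loading[sp]
            z = z + cfg.sample_log_sd * (
                sgn * math.sqrt(rho) * factors[k] + math.sqrt(1 - rho) * eps
            )
        else:
            z = z + cfg.sample_log_sd * eps
        if sp in link_of:
            link = link_of[sp]
            u = u_plant[link.variable]
            z = z + cfg.metadata_link_scale * link.direction * np.array(
                [u[plant_pos[p]] for p in plant_of]
            )
        latent[sp] = np.exp(z)

    other_total = np.sum([latent[sp] for sp in free_species], axis=0)

    # --- methanogenesis KO mass --------------------------------------------
    # The pathway mass budget tracks the panel-mean background total, not each
    # replicate's bacterial fluctuation: methanogen protein mass is a property
    # of the digester state, and a per-replicate budget would tie every
    # carrier species to the same sample-level factor, writing unplanted
    # co-occurrence structure into the table.
    sets = KoPathwaySets()
    f_vec = np.array([f_true[p] for p in plant_of])
    # Each KO mass group (acetoclastic-unique, hydrogenotrophic-unique, rest)
    # has a fixed per-sample budget; within a group the individual KO features
    # fluctuate sample-to-sample and are renormalized so the group budget —
    # and hence the acetoclastic : hydrogenotrophic ratio F — stays exact in
    # every sample.  Keeping the block total stable also damps the closure
    # denominator instead of coherently swinging it, which would otherwise
    # write spurious correlations into every taxon pair.
    M = np.full(
        n_samp,
        cfg.methanogen_fraction / (1 - cfg.methanogen_fraction) * float(other_total.mean()),
    )
    unique_mass = cfg.unique_ko_fraction * M
    aceto_mass = unique_mass * f_vec / (1 + f_vec)
    hydro_mass = unique_mass / (1 + f_vec)
    rest_mass = M - unique_mass

    def _ko_masses(kos, budget):
        """Per-KO mass vectors: fluctuating shares of an exact group budget."""
        kos = sorted(kos)
        w = rng.dirichlet(np.ones(len(kos)))[:, None]
        psi = np.exp(cfg.sample_log_sd * rng.standard_normal((len(kos), n_samp)))
        shares = w * psi
        shares /= shares.sum(axis=0, keepdims=True)
        return {k: budget * shares[i] for i, k in enumerate(kos)}

    w_aceto = _ko_masses(sets.acetoclastic_unique, aceto_mass)
    w_hydro = _ko_masses(sets.hydrogenotrophic_unique, hydro_mass)
    w_rest = _ko_masses(
        sets.common | sets.shared_aceto_hydro | sets.methylotrophic, rest_mass
    )

    features, annotations, abundance_rows = [], [], []
    name_of = names.set_index("species_id")

    def _add_feature(fid, sid, kos, values):
        features.append(fid)
        annotations.append((fid, sid, name_of.loc[sid, "species_name"],
                            name_of.loc[sid, "family"], ";".join(sorted(kos)), ""))
        abundance_rows.append(values)

    n_pg = 0
    for ko, mass in sorted(w_aceto.items()):
        n_pg += 1
        _add_feature(f"PG{n_pg:05d}", species_id(1 + (n_pg % 2)), {ko}, mass)
    for ko, mass in sorted(w_hydro.items()):
        n_pg += 1
        _add_feature(f"PG{n_pg:05d}", species_id(3 + (n_pg % 2)), {ko}, mass)
    for ko, mass in sorted(w_rest.items()):
        n_pg += 1
        _add_feature(f"PG{n_pg:05d}", species_id(1 + (n_pg % cfg.N_METHANOGENS)),
                     {ko}, mass)

    # free species protein groups; a third get an irrelevant housekeeping KO
    lo, hi = cfg.groups_per_species
    for sp in free_species:
        n_groups = int(rng.integers(lo, hi + 1))
        weights = rng.dirichlet(np.ones(n_groups))
        for g, w in enumerate(weights):
            n_pg += 1
            kos = {f"K9{(n_pg % 900) + 100:03d}"} if g % 3 == 0 else set()
            _add_feature(f"PG{n_pg:05d}", sp, kos, latent[sp] * w)

    values = np.vstack(abundance_rows)               # features x samples

    # --- noise, dropout, closure -------------------------------------------
    if cfg.noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, cfg.noise_sd, values.shape))
    if cfg.dropout_prob > 0:
        values = np.where(rng.random(values.shape) < cfg.dropout_prob, 0.0, values)

    X = pd.DataFrame(
        values.T,
        index=pd.MultiIndex.from_tuples(samples, names=SAMPLE_INDEX_NAMES),
        columns=pd.Index(features, name="feature_id"),
    )
    X = normalize_relative(X, total=100.0)

    annotation = pd.DataFrame(
        annotations,
        columns=["feature_id", "species_id", "species_name", "family", "ko_ids", "ec_ids"],
    ).set_index("feature_id")
    annotation["ko_ids"] = annotation["ko_ids"].map(
        lambda s: frozenset(s.split(";")) if s else frozenset()
    )
    annotation["ec_ids"] = annotation["ec_ids"].map(lambda s: frozenset())

    metadata = _metadata_table(cfg, u_plant, rng)

    # realized post-closure rank correlation of each planted pair
    species_totals = X.T.groupby(annotation["species_id"].values).sum().T
    realized = {
        e.pair: float(stats.spearmanr(species_totals[e.a], species_totals[e.b]).statistic)
        for e in cfg.planted_edges
    }

    truth = GroundTruth(
        f_true=f_true,
        label_true={p: classify_F(f) for p, f in f_true.items()},
        planted_edges=tuple(cfg.planted_edges),
        metadata_links=tuple(cfg.metadata_links),
        carrier_species=tuple(species_id(i) for i in range(1, cfg.N_METHANOGENS + 1)),
        realized_rho=realized,
    )
    return X, annotation, metadata, truth


def benchmark_network_config(seed: int = 1) -> SimulationConfig:
    """Default network-recovery benchmark: 30 species, 8 plants x 5 replicates
    (40 samples, all hydrogenotrophic so they form one pathway class), 10
    planted co-presence and 5 planted exclusion pairs at rho = 0.9.

    The 15 edges are laid out as 8 disjoint co-presence pairs, two (+, +, -)
    factor triples (each contributing 1 co-presence + 2 exclusion edges) and
    one disjoint exclusion pair, using 24 of the 26 non-methanogen species.
    """
    free = [species_id(i) for i in range(5, 31)]
    edges = [PlantedEdge(free[2 * k], free[2 * k + 1], sign=1, rho=0.9)
             for k in range(8)]                       # 8 co-presence pairs
    for a, b, c in (free[16:19], free[19:22]):        # two (+, +, -) triples
        edges += [PlantedEdge(a, b, sign=1, rho=0.9),
                  PlantedEdge(a, c, sign=-1, rho=0.9),
                  PlantedEdge(b, c, sign=-1, rho=0.9)]
    edges.append(PlantedEdge(free[22], free[23], sign=-1, rho=0.9))
    return SimulationConfig(
        n_plants=8,
        n_replicates=5,
        n_species=30,
        f_true={f"BP{i:02d}": 0.1 for i in range(1, 9)},
        planted_edges=tuple(edges),
        dropout_prob=0.02,
        noise_sd=0.3,
        seed=seed,
    )


def recovery_report(
    truth: GroundTruth,
    pathway_labels: dict | None = None,
    graph=None,
    correlations: pd.DataFrame | None = None,
    alpha: float = 0.01,
) -> dict:
    """Compare pipeline outputs against the generator's ground truth.

    Returns a dict with (where the corresponding output was supplied)
    ``label_accuracy``, planted-edge ``edge_recall`` / ``edge_precision``
    (sign must match), and ``metadata_link_recall`` at the screen's alpha.
    """
    metrics: dict = {}
    if pathway_labels is not None:
        plants = list(truth.label_true)
        hits = sum(pathway_labels.get(p) == truth.label_true[p] for p in plants)
        metrics["label_accuracy"] = hits / len(plants) if plants else float("nan")
    if graph is not None:
        planted = {e.pair: e.sign for e in truth.planted_edges}
        carriers = set(truth.carrier_species)
        found = {tuple(sorted((a, b))): data.get("sign", 1)
                 for a, b, data in graph.edges(data=True)
                 if not ({a, b} & carriers)}
        true_pos = sum(1 for pair, sign in planted.items() if found.get(pair) == sign)
        metrics["edge_recall"] = true_pos / len(planted) if planted else float("nan")
        metrics["edge_precision"] = true_pos / len(found) if found else 0.0
        metrics["n_edges_found"] = len(found)
    if correlations is not None:
        n_hit = 0
        for link in truth.metadata_links:
            rec = correlations[
                (correlations["feature"] == link.species)
                & (correlations["variable"] == link.variable)
            ]
            if len(rec) and float(rec["p"].iloc[0]) <= alpha and (
                np.sign(float(rec["rho"].iloc[0])) == link.direction
            ):
                n_hit += 1
        if truth.metadata_links:
            metrics["metadata_link_recall"] = n_hit / len(truth.metadata_links)
    return metrics


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a config with a different master seed."""
    return replace(cfg, seed=seed)
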