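"""Ground-truth-labelled synthetic data with the structure the pipeline assumes.

Three generators cover the study design end to end:

* ultrametric host and symbiont phylogenies (Yule process),
* a paired marker alignment in which a sub-region (the fast-evolving D2
  analogue) evolves at a tunable multiple of the whole-marker rate, and
* gut communities assembled from a log-series regional pool under a
  controlled mixture of selection (strength ``sigma_s``), drift (local
  community size ``J``) and homogenizing dispersal (rate ``m``), with the
  host-filter coupling to the host phylogeny controlled by a single
  phylosymbiosis knob ``rho``.

Every random draw flows from one integer seed through
``numpy.random.SeedSequence`` substreams; there is no hidden global state.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from dendropy.simulate import treesim
from skbio import TreeNode

from .core import (
    Alignment,
    CommunityTable,
    tree_height,
    validate_metadata,
    write_alignment,
    write_community_table,
    write_metadata,
    write_tree,
)

COUNTRIES = ("USA", "Egypt", "Italy", "New Zealand", "Germany", "Nepal")


@dataclass
class SyntheticTruth:
    """The generating parameters serialized alongside every dataset."""

    selection_strength: float = 2.0   # sigma_s; 0 = neutral
    dispersal_rate: float = 0.05      # m in [0, 1]
    local_community_size: int = 1000  # J individuals per sample
    phylosymbiosis_strength: float = 1.0  # rho in [0, 1]
    rate_ratio: float = 1.75          # sub-region / whole-marker rate
    fisher_alpha: float = 10.0        # skew of the regional log-series pool
    selection_target: float = 0.0     # shared offset of host niche positions
    seed: int = 0

    def __post_init__(self):
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if not 0 <= self.dispersal_rate <= 1:
            raise ValueError("dispersal_rate must be in [0, 1]")
        if self.local_community_size <= 0:
            raise ValueError("local_community_size must be positive")
        if not 0 <= self.phylosymbiosis_strength <= 1:
            raise ValueError("phylosymbiosis_strength must be in [0, 1]")
        if self.rate_ratio <= 0:
            raise ValueError("rate_ratio must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class MarkerPair:
    """Full-length marker alignment and its faster-evolving suffix sub-region."""

    full: Alignment
    sub_start: int

    @property
    def sub(self) -> Alignment:
        return self.full.slice(self.sub_start)

    @property
    def taxon_ids(self) -> list[str]:
        return self.full.ids


# ---------------------------------------------------------------------------
# phylogeny simulation
# ---------------------------------------------------------------------------

def simulate_phylogeny(
    n_tips: int, model: str = "yule", seed: int = 0, tip_prefix: str = "T"
) -> TreeNode:
    """Ultrametric rooted tree under a pure-birth (Yule) process, height 1."""
    if model != "yule":
        raise ValueError(f"unknown model {model!r}")
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if n_tips == 2:  # the birth process has no waiting time to simulate
        tree = TreeNode.read(StringIO(f"({tip_prefix}1:1,{tip_prefix}2:1);"))
        tree.length = 0.0
        return tree
    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=random.Random(int(seed)),
    )
    dtree.seed_node.edge.length = 0.0
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read(StringIO(newick), format="newick")
    tree.length = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    # normalize to height 1 and give tips stable, prefix-based labels
    h = tree_height(tree)
    if h <= 0:
        raise ValueError("degenerate simulated tree of zero height")
    for node in tree.traverse(include_self=False):
        node.length /= h
    width = len(str(n_tips))
    for i, tip in enumerate(tree.tips(), start=1):
        tip.name = f"{tip_prefix}{i:0{width}d}"
    return tree


def brownian_traits(tree: TreeNode, rng: np.random.Generator, standardize: bool = True) -> pd.Series:
    """One Brownian-motion trait value per tip (variance = path length)."""
    values = {}

    def _walk(node, x):
        for child in node.children:
            step = rng.normal(0.0, np.sqrt(max(child.length or 0.0, 0.0)))
            if child.is_tip():
                values[child.name] = x + step
            else:
                _walk(child, x + step)

    _walk(tree, 0.0)
    s = pd.Series(values, dtype=float)
    s = s[[t.name for t in tree.tips()]]
    if standardize:
        sd = s.std(ddof=0)
        s = (s - s.mean()) / (sd if sd > 0 else 1.0)
    return s


def conserved_niche_trait(tree: TreeNode) -> pd.Series:
    """Standardized first principal coordinate of the patristic matrix.

    The most phylogenetically conserved one-dimensional niche axis a tree
    admits: tips close on the tree are close on the axis by construction, so
    a selection filter over this trait always targets a low-diameter clade.
    Deterministic given the tree (no Brownian sampling noise).
    """
    from .core import patristic_distances
    from .structure import pcoa

    ord_res = pcoa(patristic_distances(tree))
    v = ord_res.coordinates.iloc[:, 0]
    sd = v.std(ddof=0)
    v = (v - v.mean()) / (sd if sd > 0 else 1.0)
    # fix the arbitrary eigenvector sign: first tip non-negative
    if v.iloc[0] < 0:
        v = -v
    return v


# ---------------------------------------------------------------------------
# marker-pair simulation (Jukes-Cantor, two rate classes)
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_marker_pair(
    tree: TreeNode,
    len_full: int = 700,
    sub_start: int = 330,
    rate_ratio: float = 1.75,
    mean_rate: float = 0.05,
    seed: int = 0,
) -> MarkerPair:
    """Evolve an alignment along ``tree`` under Jukes-Cantor.

    Columns ``[sub_start:]`` (the sub-region) evolve at ``rate_ratio`` times
    the *average* rate of the full alignment; the leading columns absorb the
    complement so the whole-marker mean rate equals ``mean_rate``
    substitutions per site per unit branch length.
    """
    if rate_ratio <= 0:
        raise ValueError("rate_ratio must be positive")
    if not 0 <= sub_start < len_full:
        raise ValueError("sub_start must satisfy 0 <= sub_start < len_full")
    L, Ls = len_full, len_full - sub_start
    if rate_ratio * Ls >= L and Ls < L:
        raise ValueError(
            f"rate_ratio {rate_ratio} too large for sub-region fraction {Ls}/{L}: "
            "the leading-region rate would be negative"
        )
    r_sub = rate_ratio * mean_rate
    r_head = mean_rate * (L - rate_ratio * Ls) / (L - Ls) if Ls < L else r_sub
    site_rates = np.full(L, r_head)
    site_rates[sub_start:] = r_sub

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    root_seq = rng.integers(0, 4, size=L)
    seqs: dict[str, np.ndarray] = {}

    def _evolve(node, seq):
        for child in node.children:
            t = max(child.length or 0.0, 0.0)
            p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * site_rates * t))
            hit = rng.random(L) < p_change
            new = seq.copy()
            if hit.any():
                # substitute with one of the three other bases, uniformly
                new[hit] = (new[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            if child.is_tip():
                seqs[child.name] = new
            else:
                _evolve(child, new)

    _evolve(tree, root_seq)
    ids = [t.name for t in tree.tips()]
    mat = _BASES[np.vstack([seqs[i] for i in ids])]
    return MarkerPair(Alignment(ids, mat), sub_start)


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def logseries_pool(n_taxa: int, fisher_alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Log-skewed regional relative abundances (log-series counts, normalized).

    The shape parameter follows Fisher's relation S = alpha ln(1 + N/alpha):
    solving for the community size N that yields ``n_taxa`` species at the
    given alpha gives ``x = 1 - exp(-n_taxa / alpha)``. Small alpha (default
    10) therefore produces a few dominant genera and a long tail of
    perpetually rare ones, the shape real genus pools show.
    """
    x = 1.0 - np.exp(-n_taxa / float(fisher_alpha))
    counts = rng.logseries(x, size=n_taxa).astype(float)
    return counts / counts.sum()


def assemble_communities(
    host_tree: TreeNode,
    symbiont_tree: TreeNode,
    n_individuals_per_species,
    truth: SyntheticTruth,
    species_attributes: pd.DataFrame | None = None,
) -> tuple[CommunityTable, pd.DataFrame, dict]:
    """Draw per-sample communities under selection, drift and dispersal.

    Per host species ``h`` with environmental position
    ``rho * x_h + selection_target`` (``x_h`` the host tree's conserved niche
    axis) and per genus ``g`` with conserved niche trait ``t_g`` on the
    symbiont tree, the host filter is
    ``w(g, h) = exp(-sigma_s * (t_g - rho * x_h - target)^2)``. A sample is
    a multinomial draw of ``J`` individuals from ``pool * w`` (drift), with a
    binomial ``m`` fraction of the draw replaced by draws from the
    metacommunity mean (homogenizing dispersal). ``sigma_s = 0`` is the
    neutral limit; ``rho = 0`` with ``sigma_s > 0`` is pure shared
    (homogeneous) selection; ``rho = 1`` couples the filter to the host
    phylogeny (phylosymbiosis).

    Returns the community table, the per-sample metadata, and the latent
    state (pool, traits, positions) for truth-aware tests.
    """
    species = [t.name for t in host_tree.tips()]
    genera = [t.name for t in symbiont_tree.tips()]
    if not genera:
        raise ValueError("empty regional pool")
    J = int(truth.local_community_size)
    if J <= 0:
        raise ValueError("local community size J must be positive")
    if isinstance(n_individuals_per_species, int):
        reps = {sp: n_individuals_per_species for sp in species}
    else:
        reps = dict(n_individuals_per_species)
        unknown = set(reps) - set(species)
        if unknown:
            raise ValueError(f"replication given for unknown species: {sorted(unknown)}")

    ss = np.random.SeedSequence(truth.seed)
    rng_pool, rng_traits, rng_pos, rng_comm, rng_meta = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    pool = logseries_pool(len(genera), truth.fisher_alpha, rng_pool)
    traits = conserved_niche_trait(symbiont_tree).to_numpy()
    host_x = conserved_niche_trait(host_tree)
    del rng_traits, rng_pos  # niche axes are deterministic given the trees
    sigma = truth.selection_strength
    rho = truth.phylosymbiosis_strength
    m = truth.dispersal_rate

    probs = {}
    for sp in species:
        delta = traits - (rho * host_x[sp] + truth.selection_target)
        w = np.exp(-sigma * delta**2)
        p = pool * w
        tot = p.sum()
        if tot <= 0:
            raise ValueError(f"host filter removed the entire pool for {sp}")
        probs[sp] = p / tot
    meta_mean = np.mean([probs[sp] for sp in species], axis=0)
    meta_mean = meta_mean / meta_mean.sum()

    rows, sample_ids, meta_rows = [], [], []
    attrs = species_attributes if species_attributes is not None else _default_species_attributes(
        host_tree, rng_meta
    )
    for sp in species:
        for k in range(reps.get(sp, 0)):
            n_local = rng_comm.binomial(J, 1.0 - m)
            comm = rng_comm.multinomial(n_local, probs[sp]) + rng_comm.multinomial(
                J - n_local, meta_mean
            )
            sid = f"{sp}_{k + 1:02d}"
            rows.append(comm)
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "species": sp,
                    "family": attrs.loc[sp, "family"],
                    "gut_type": attrs.loc[sp, "gut_type"],
                    "domestication": attrs.loc[sp, "domestication"],
                    "country": rng_meta.choice(COUNTRIES),
                    "age": rng_meta.choice(["juvenile", "adult", "aged"]),
                    "sex": rng_meta.choice(["female", "male"]),
                }
            )
    if not rows:
        raise ValueError("no samples requested")
    table = CommunityTable(
        pd.DataFrame(np.vstack(rows), index=sample_ids, columns=genera)
    )
    meta = validate_metadata(pd.DataFrame(meta_rows))
    latent = {"pool": pool, "traits": traits, "host_positions": rho * host_x, "probs": probs}
    return table, meta, latent


def _default_species_attributes(host_tree: TreeNode, rng: np.random.Generator) -> pd.DataFrame:
    species = [t.name for t in host_tree.tips()]
    n_fam = min(3, len(species))
    fam = assign_clades(host_tree, n_fam, prefix="F")
    gut = {f: ("ruminant", "pseudoruminant", "hindgut")[i % 3]
           for i, f in enumerate(sorted(set(fam.values())))}
    return pd.DataFrame(
        {
            "family": [fam[sp] for sp in species],
            "gut_type": [gut[fam[sp]] for sp in species],
            "domestication": [
                "domesticated" if rng.random() < 0.7 else "non-domesticated" for _ in species
            ],
        },
        index=species,
    )


def _assign_gut_types(families: list[str], family_totals: dict[str, int]) -> dict[str, str]:
    """Map families to gut types with sample proportions like real herbivore
    panels: one small pseudoruminant family (~2.5% of samples), hindgut
    families covering ~27%, ruminants the rest.

    Deterministic given the family sample totals.
    """
    total = sum(family_totals.values())
    pseudo = min(families, key=lambda f: (abs(family_totals[f] - 0.025 * total), f))
    gut = {pseudo: "pseudoruminant"}
    remaining = [f for f in families if f != pseudo]
    hindgut_total, target = 0, 0.27 * total
    for f in sorted(remaining, key=lambda f: (-family_totals[f], f)):
        if len(gut) + 1 == len(families):
            break  # keep at least one ruminant family
        if hindgut_total + family_totals[f] <= 1.3 * target:
            gut[f] = "hindgut"
            hindgut_total += family_totals[f]
        if hindgut_total >= 0.75 * target:
            break
    if hindgut_total == 0 and len(remaining) > 1:
        smallest = min(remaining, key=lambda f: (family_totals[f], f))
        gut[smallest] = "hindgut"
    for f in remaining:
        gut.setdefault(f, "ruminant")
    return gut


def assign_clades(tree: TreeNode, n_groups: int, prefix: str = "F") -> dict[str, str]:
    """Partition tips into ``n_groups`` phylogenetically coherent groups.

    Average-linkage clustering of the patristic distances, so groups are
    (near-)clades; deterministic given the tree.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    from .core import patristic_distances

    dm = patristic_distances(tree)
    tips = list(dm.ids)
    if n_groups >= len(tips):
        return {t: f"{prefix}{i + 1}" for i, t in enumerate(tips)}
    Z = linkage(squareform(dm.data, checks=False), method="average")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    # stable group names in order of first appearance along the tip order
    remap, out = {}, {}
    for tip, lab in zip(tips, labels):
        if lab not in remap:
            remap[lab] = f"{prefix}{len(remap) + 1}"
        out[tip] = remap[lab]
    return out


# ---------------------------------------------------------------------------
# study fixtures
# ---------------------------------------------------------------------------

# Unbalanced per-species replication mimicking the study design: 661 samples
# over 34 species with a few heavily sampled livestock species and a long
# tail of rarely sampled hosts.
_PAPER_SHAPE_REPLICATION = [
    229, 138, 96, 71, 23, 16, 10, 9, 8, 7, 6, 5, 5, 4, 4, 3, 3, 3, 2, 2, 2,
    2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1,
]
assert sum(_PAPER_SHAPE_REPLICATION) == 661 and len(_PAPER_SHAPE_REPLICATION) == 34

PRESETS = {
    "small": {"n_species": 6, "n_families": 3, "n_genera": 40, "replication": 3},
    "medium": {"n_species": 12, "n_families": 4, "n_genera": 60, "replication": 3},
    "paper_shape": {
        "n_species": 34,
        "n_families": 9,
        "n_genera": 87,
        "replication": _PAPER_SHAPE_REPLICATION,
    },
}


@dataclass
class StudyFixture:
    """Everything one analysis run consumes, plus the generating truth."""

    host_tree: TreeNode
    symbiont_tree: TreeNode
    markers: MarkerPair
    table: CommunityTable
    metadata: pd.DataFrame
    truth: SyntheticTruth
    latent: dict = field(repr=False, default_factory=dict)


def make_study_fixture(
    preset: str = "small", seed: int = 0, replication=None, **truth_overrides
) -> StudyFixture:
    """One-call fixture: trees, markers, communities and metadata.

    ``truth_overrides`` adjust :class:`SyntheticTruth` knobs (e.g.
    ``selection_strength=0`` for the neutral limit); ``replication``
    overrides the preset's per-species sample count.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    ss = np.random.SeedSequence(int(seed))
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]
    truth = SyntheticTruth(seed=seeds[0], **truth_overrides)

    host_tree = simulate_phylogeny(cfg["n_species"], seed=seeds[1], tip_prefix="sp")
    symbiont_tree = simulate_phylogeny(cfg["n_genera"], seed=seeds[2], tip_prefix="g")
    markers = simulate_marker_pair(symbiont_tree, rate_ratio=truth.rate_ratio, seed=seeds[3])

    species = [t.name for t in host_tree.tips()]
    fam = assign_clades(host_tree, cfg["n_families"], prefix="F")
    families = sorted({fam[sp] for sp in species})

    rep = replication if replication is not None else cfg["replication"]
    if isinstance(rep, int):
        reps = {sp: rep for sp in species}
    else:
        reps = {sp: r for sp, r in zip(species, rep)}
    gut_of_family = _assign_gut_types(
        families, {f: sum(reps[sp] for sp in species if fam[sp] == f) for f in families}
    )
    rng_attr = np.random.default_rng(ss.spawn(1)[0])
    dom = ["domesticated" if rng_attr.random() < 0.85 else "non-domesticated"
           for _ in species]
    if len(set(dom)) == 1 and len(species) >= 2:  # keep the factor testable
        dom[-1] = "non-domesticated" if dom[0] == "domesticated" else "domesticated"
    attrs = pd.DataFrame(
        {
            "family": [fam[sp] for sp in species],
            "gut_type": [gut_of_family[fam[sp]] for sp in species],
            "domestication": dom,
        },
        index=species,
    )

    table, meta, latent = assemble_communities(
        host_tree, symbiont_tree, reps, truth, species_attributes=attrs
    )
    return StudyFixture(host_tree, symbiont_tree, markers, table, meta, truth, latent)


def write_fixture(fixture: StudyFixture, out_dir) -> dict[str, str]:
    """Serialize a fixture to the standard on-disk formats; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "table.tsv",
        "metadata": out / "metadata.tsv",
        "host_tree": out / "host.nwk",
        "symbiont_tree": out / "symbiont.nwk",
        "markers_full": out / "markers_full.fasta",
        "markers_sub": out / "markers_sub.fasta",
        "truth": out / "truth.yaml",
    }
    write_community_table(fixture.table, paths["table"])
    write_metadata(fixture.metadata, paths["metadata"])
    write_tree(fixture.host_tree, paths["host_tree"])
    write_tree(fixture.symbiont_tree, paths["symbiont_tree"])
    write_alignment(fixture.markers.full, paths["markers_full"])
    write_alignment(fixture.markers.sub, paths["markers_sub"])
    fixture.truth.to_yaml(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
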