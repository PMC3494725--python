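"""Synthetic coevolution datasets: species tree, gene trees, profiles, labels.

The simulator emulates the data regime the predictor is designed for: one
reference species phylogeny, per-protein ortholog presence/absence over the
species set, and per-protein gene trees, with interacting pairs coupled and
everything else evolving independently.  Two coupling channels inject
signal into the two feature families separately:

* **shared gene loss** - each branch of the species tree can carry a loss
  event killing the whole clade below it.  For an interacting pair a loss
  is shared by both proteins with probability ``rho_loss`` (per-branch
  shared events at rate ``rho_loss * loss_rate`` plus private events at
  rate ``(1 - rho_loss) * loss_rate``, keeping the marginal per-branch loss
  probability at ``loss_rate`` up to second order).  This drives the
  phylogenetic-profile features.

* **correlated rate noise** - per-branch lognormal rate multipliers with a
  fraction ``rate_coupling`` of their log-variance shared within a pair.
  Gene trees are the species tree pruned to the surviving species with
  branch lengths multiplied by the protein's rates; this drives the
  mirror/congruence features.

At ``rho_loss = rate_coupling = 1`` an interacting pair has identical
profiles and identical gene trees; at 0 the labels carry no signal.

Default class imbalance is ~0.8% positives, the regime of a curated
complex-membership gold standard.  Proteins that would fail the pipeline's
own >= 7-species inclusion rules are resampled so the requested pair
counts are delivered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import dendropy
import numpy as np

from .datamodel import (
    GeneTree,
    PairLabel,
    PhyloProfile,
    SpeciesUniverse,
    ValidationError,
    write_newick,
    write_pair_labels,
    write_profiles,
)

logger = logging.getLogger("coevoppi")

__all__ = [
    "SimulationConfig",
    "simulate_species_tree",
    "simulate_pair",
    "simulate_dataset",
    "generate_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults: 115 genomes (the scale of the prokaryotic ortholog panel the
    method targets), ~0.8% positive pairs, per-branch loss probability 0.05,
    strong coupling (rho_loss 0.9, rate_coupling 0.8) and moderate lognormal
    rate noise (sigma 0.3).
    """

    n_species: int = 115
    n_pos_pairs: int = 8
    n_neg_pairs: int = 992
    loss_rate: float = 0.05
    rho_loss: float = 0.9
    rate_noise: float = 0.3
    rate_coupling: float = 0.8
    birth_rate: float = 1.0
    min_species: int = 7
    max_retries: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 10:
            raise ValidationError("n_species must be >= 10")
        for name in ("loss_rate", "rho_loss", "rate_coupling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.rate_noise < 0:
            raise ValidationError("rate_noise must be >= 0")


def simulate_species_tree(
    n_species: int, seed: int | np.random.Generator = 0, birth_rate: float = 1.0
) -> GeneTree:
    """Ultrametric Yule (pure-birth) species tree with n tips.

    Waiting times between successive speciations with k extant lineages are
    Exponential(k * birth_rate); the expected root-to-tip depth therefore
    grows like (harmonic(n) - 1) / birth_rate.  Deterministic given seed.
    """
    if n_species < 10:
        raise ValidationError("n_species must be >= 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    birth_time: dict[int, float] = {}
    t = 0.0
    active: list[dendropy.Node] = []
    for _ in range(2):
        ch = dendropy.Node()
        root.add_child(ch)
        birth_time[id(ch)] = 0.0
        active.append(ch)
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        nd = active.pop(int(rng.integers(k)))
        nd.edge.length = t - birth_time[id(nd)]
        for _ in range(2):
            ch = dendropy.Node()
            nd.add_child(ch)
            birth_time[id(ch)] = t
            active.append(ch)
    t_final = t + rng.exponential(1.0 / (n_species * birth_rate))
    width = len(str(n_species - 1))
    for i, nd in enumerate(active):
        nd.edge.length = t_final - birth_time[id(nd)]
        nd.taxon = taxa.new_taxon(label=f"S{i:0{width}d}")
    return GeneTree(protein_id="species_tree", tree=tree)


def _species_edges(tree: dendropy.Tree) -> list[dendropy.Edge]:
    """Non-root edges in a fixed preorder, the canonical event indexing."""
    return [
        nd.edge for nd in tree.preorder_node_iter() if nd.parent_node is not None
    ]


def _surviving(tree: dendropy.Tree, loss: np.ndarray) -> list[str]:
    """Leaves below no loss event; loss is indexed like _species_edges."""
    edge_idx = {id(e): i for i, e in enumerate(_species_edges(tree))}
    lost: dict[int, bool] = {}
    out = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            lost[id(nd)] = False
            continue
        lost[id(nd)] = lost[id(nd.parent_node)] or bool(loss[edge_idx[id(nd.edge)]])
        if nd.is_leaf() and not lost[id(nd)]:
            out.append(nd.taxon.label)
    return out


def _gene_tree(
    species_tree: GeneTree,
    multipliers: np.ndarray,
    surviving: list[str],
    protein_id: str,
) -> GeneTree:
    t = species_tree.tree.clone(depth=1)
    for edge, m in zip(_species_edges(t), multipliers):
        edge.length = edge.length * m
    pruned = t.extract_tree_with_taxa_labels(labels=set(surviving))
    return GeneTree(protein_id=protein_id, tree=pruned)


def simulate_pair(
    species_tree: GeneTree,
    interacting: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
    protein_ids: tuple[str, str] = ("A", "B"),
    universe: SpeciesUniverse | None = None,
) -> tuple[GeneTree, GeneTree, PhyloProfile, PhyloProfile]:
    """One protein pair: two gene trees and two profiles.

    Retries until both proteins survive in >= min_species species and share
    >= min_species species (the pipeline's own eligibility rules); errors
    out after max_retries attempts.
    """
    if universe is None:
        universe = SpeciesUniverse(tuple(sorted(species_tree.leaf_labels())))
    n_edges = len(_species_edges(species_tree.tree))
    rho = config.rho_loss if interacting else 0.0
    coup = config.rate_coupling if interacting else 0.0
    sigma = config.rate_noise
    idx = universe.index()

    for _ in range(config.max_retries):
        shared = rng.random(n_edges) < rho * config.loss_rate
        loss_a = shared | (rng.random(n_edges) < (1.0 - rho) * config.loss_rate)
        loss_b = shared | (rng.random(n_edges) < (1.0 - rho) * config.loss_rate)
        z_shared = rng.standard_normal(n_edges)
        mult_a = np.exp(
            sigma * (np.sqrt(coup) * z_shared
                     + np.sqrt(1.0 - coup) * rng.standard_normal(n_edges))
        )
        mult_b = np.exp(
            sigma * (np.sqrt(coup) * z_shared
                     + np.sqrt(1.0 - coup) * rng.standard_normal(n_edges))
        )
        surv_a = _surviving(species_tree.tree, loss_a)
        surv_b = _surviving(species_tree.tree, loss_b)
        overlap = len(set(surv_a) & set(surv_b))
        if (
            len(surv_a) < config.min_species
            or len(surv_b) < config.min_species
            or overlap < config.min_species
        ):
            continue
        pa = np.zeros(universe.N, dtype=np.uint8)
        pa[[idx[s] for s in surv_a]] = 1
        pb = np.zeros(universe.N, dtype=np.uint8)
        pb[[idx[s] for s in surv_b]] = 1
        return (
            _gene_tree(species_tree, mult_a, surv_a, protein_ids[0]),
            _gene_tree(species_tree, mult_b, surv_b, protein_ids[1]),
            PhyloProfile(protein_ids[0], pa, universe),
            PhyloProfile(protein_ids[1], pb, universe),
        )
    raise ValidationError(
        f"could not draw an eligible pair in {config.max_retries} attempts "
        "(loss_rate too high for this species tree?)"
    )


def simulate_dataset(config: SimulationConfig) -> dict:
    """In-memory dataset: species tree, gene trees, profiles and labels.

    Each simulated pair introduces two fresh proteins, so pairs are
    independent of each other; positives are listed first.  Deterministic
    given config.seed.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_seed, pair_seed = ss.spawn(2)
    species_tree = simulate_species_tree(
        config.n_species, np.random.default_rng(tree_seed), config.birth_rate
    )
    universe = SpeciesUniverse(tuple(sorted(species_tree.leaf_labels())))
    rng = np.random.default_rng(pair_seed)

    n_total = config.n_pos_pairs + config.n_neg_pairs
    width = len(str(2 * n_total - 1))
    trees: dict[str, GeneTree] = {}
    profiles: dict[str, PhyloProfile] = {}
    labels: list[PairLabel] = []
    for i in range(n_total):
        interacting = i < config.n_pos_pairs
        ids = (f"P{2 * i:0{width}d}", f"P{2 * i + 1:0{width}d}")
        ta, tb, pa, pb = simulate_pair(
            species_tree, interacting, config, rng, ids, universe
        )
        trees[ids[0]] = ta
        trees[ids[1]] = tb
        profiles[ids[0]] = pa
        profiles[ids[1]] = pb
        labels.append(PairLabel(ids[0], ids[1], "pos" if interacting else "neg"))
    logger.info(
        "simulated %d pairs (%d pos / %d neg) over %d species",
        n_total, config.n_pos_pairs, config.n_neg_pairs, config.n_species,
    )
    return {
        "species_tree": species_tree,
        "universe": universe,
        "trees": trees,
        "profiles": profiles,
        "labels": labels,
        "config": config,
    }


def generate_dataset(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset in the exact formats the pipeline consumes:
    trees/<protein>.nwk, profiles.tsv, labels.tsv, tol.nwk (+ config.json)."""
    out = Path(out_dir)
    data = simulate_dataset(config)
    tree_dir = out / "trees"
    tree_dir.mkdir(parents=True, exist_ok=True)
    for pid, gt in sorted(data["trees"].items()):
        write_newick(gt, tree_dir / f"{pid}.nwk")
    write_profiles(
        [data["profiles"][k] for k in sorted(data["profiles"])],
        out / "profiles.tsv",
    )
    write_pair_labels(data["labels"], out / "labels.tsv")
    write_newick(data["species_tree"], out / "tol.nwk")
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")
    return {
        "trees": tree_dir,
        "profiles": out / "profiles.tsv",
        "labels": out / "labels.tsv",
        "tol": out / "tol.nwk",
        "config": out / "config.json",
    }
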