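"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Three generators, all fully seeded:

* :func:`make_alignment` — a two-family protein alignment with a planted
  differential-conservation category per column, planted insertion blocks,
  an optional planted C-terminal extension of family A, and i.i.d. uniform
  substitution noise.  The truth labels travel with the alignment so the
  consensus/classification pipeline can be tested closed-loop.
* :func:`make_table` — a taxon x factor presence table, either from a
  ratchet history simulated on a Yule tree (recent losses re-labelled
  DIVERGENT, mimicking genes caught mid-decay) or from independent Bernoulli
  draws (the null model for calibrating the association test).
* :func:`make_tree` — a seeded Yule (pure-birth) phylogeny rescaled to a
  chosen height.

The noise model is deliberately minimal — independent uniform substitution
over the other 19 residues, no within-family phylogenetic correlation — it
stresses the consensus threshold logic, not alignment realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from . import ratchet
from .conservation import AMINO_ACIDS, LabelledAlignment, SiteCategory
from .factors import FactorTable, State

__all__ = [
    "AlignmentRecipe",
    "AlignmentTruth",
    "TableRecipe",
    "make_alignment",
    "make_table",
    "make_tree",
]

_DEFAULT_FRACTIONS = {
    SiteCategory.STRONG_DIFFERENTIAL: 0.10,
    SiteCategory.CONSERVED_A_ONLY: 0.10,
    SiteCategory.CONSERVED_B_ONLY: 0.10,
    SiteCategory.IDENTICALLY_CONSERVED: 0.50,
    SiteCategory.UNCONSERVED: 0.20,
}


@dataclass
class AlignmentRecipe:
    """Recipe for a planted-truth two-family alignment.

    ``length`` is the total number of columns, including any columns claimed
    by ``planted_insertions`` — each of those is a (start, end, family)
    triple in 0-based half-open column coordinates, ``family`` naming the
    family that CARRIES residues there (the other family is gapped).
    ``tail_length_A`` appends that many extra columns where only family A
    has residues, emulating eEF1A's C-terminal extension.  ``noise`` is the
    per-cell probability of substituting a residue uniformly by one of the
    other 19.
    """

    n_a: int = 20
    n_b: int = 20
    length: int = 200
    category_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    planted_insertions: list = field(default_factory=list)
    noise: float = 0.0
    tail_length_a: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("need at least 2 sequences per family")
        if not (0 <= self.noise < 0.5):
            raise ValueError("noise must be in [0, 0.5)")
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions sum to {total}, not 1")
        spans = sorted((s, e) for s, e, _ in self.planted_insertions)
        for (s, e), nxt in zip(spans, spans[1:] + [(self.length, self.length)]):
            if not (0 <= s < e <= self.length):
                raise ValueError(f"insertion interval ({s}, {e}) outside alignment")
            if e > nxt[0]:
                raise ValueError("insertion intervals overlap")


@dataclass
class AlignmentTruth:
    """Planted ground truth accompanying a generated alignment."""

    categories: list[SiteCategory]  # per column, INDEL for insertion/tail cols
    residue_pairs: list  # per column (resA, resB) or None
    insertions: list  # (start, end, carrier family) as planted
    tail_length_a: int

    def to_tsv(self) -> str:
        lines = ["column\tcategory\tresA\tresB"]
        for i, (cat, pair) in enumerate(zip(self.categories, self.residue_pairs)):
            ra, rb = pair if pair else (".", ".")
            lines.append(f"{i + 1}\t{cat.value}\t{ra}\t{rb}")
        return "\n".join(lines) + "\n"


def _cycle_column(n: int, rng: np.random.Generator) -> list[str]:
    """n residues with every letter count within 1 of n/20.

    Guarantees no residue reaches 50% frequency for n >= 3 (and at most 50%
    at n = 2), so the column can never be called conserved at the 70% tier.
    """
    reps = -(-n // 20)
    pool = list(AMINO_ACIDS) * reps
    rng.shuffle(pool)
    return pool[:n]


def make_alignment(recipe: AlignmentRecipe):
    """Generate (LabelledAlignment, AlignmentTruth); deterministic per seed."""
    rng = np.random.default_rng(recipe.seed)
    n_a, n_b = recipe.n_a, recipe.n_b
    total = recipe.length + recipe.tail_length_a

    indel_cols: dict[int, str] = {}
    for s, e, fam in recipe.planted_insertions:
        for c in range(s, e):
            indel_cols[c] = fam
    for c in range(recipe.length, total):
        indel_cols[c] = "A"  # C-terminal tail: A carries residues, B gapped

    cats = list(recipe.category_fractions)
    probs = np.array([recipe.category_fractions[c] for c in cats])

    cols_a: list[list[str]] = []
    cols_b: list[list[str]] = []
    truth_cats: list[SiteCategory] = []
    truth_pairs: list = []
    for col in range(total):
        if col in indel_cols:
            carrier = indel_cols[col]
            res = AMINO_ACIDS[rng.integers(20)]
            col_a = [res] * n_a if carrier == "A" else ["-"] * n_a
            col_b = [res] * n_b if carrier == "B" else ["-"] * n_b
            truth_cats.append(SiteCategory.INDEL)
            truth_pairs.append((res, "-") if carrier == "A" else ("-", res))
        else:
            cat = cats[rng.choice(len(cats), p=probs)]
            truth_cats.append(cat)
            if cat is SiteCategory.STRONG_DIFFERENTIAL:
                ra, rb = rng.choice(20, size=2, replace=False)
                ra, rb = AMINO_ACIDS[ra], AMINO_ACIDS[rb]
                col_a, col_b = [ra] * n_a, [rb] * n_b
            elif cat is SiteCategory.IDENTICALLY_CONSERVED:
                ra = rb = AMINO_ACIDS[rng.integers(20)]
                col_a, col_b = [ra] * n_a, [rb] * n_b
            elif cat is SiteCategory.CONSERVED_A_ONLY:
                ra, rb = AMINO_ACIDS[rng.integers(20)], None
                col_a, col_b = [ra] * n_a, _cycle_column(n_b, rng)
            elif cat is SiteCategory.CONSERVED_B_ONLY:
                ra, rb = None, AMINO_ACIDS[rng.integers(20)]
                col_a, col_b = _cycle_column(n_a, rng), [rb] * n_b
            elif cat is SiteCategory.UNCONSERVED:
                ra = rb = None
                col_a, col_b = _cycle_column(n_a, rng), _cycle_column(n_b, rng)
            else:
                raise ValueError(f"cannot plant category {cat}")
            truth_pairs.append((ra, rb))
        cols_a.append(col_a)
        cols_b.append(col_b)

    def assemble(cols: list[list[str]], n: int) -> list[str]:
        seqs = []
        for i in range(n):
            seqs.append("".join(col[i] for col in cols))
        return seqs

    seqs_a = assemble(cols_a, n_a)
    seqs_b = assemble(cols_b, n_b)

    if recipe.noise > 0:
        def perturb(seqs: list[str]) -> list[str]:
            out = []
            for s in seqs:
                chars = list(s)
                for i, ch in enumerate(chars):
                    if ch != "-" and rng.random() < recipe.noise:
                        alt = AMINO_ACIDS.replace(ch, "")
                        chars[i] = alt[rng.integers(19)]
                out.append("".join(chars))
            return out

        seqs_a = perturb(seqs_a)
        seqs_b = perturb(seqs_b)

    aln = LabelledAlignment(
        ids=[f"A_{i:03d}" for i in range(n_a)] + [f"B_{i:03d}" for i in range(n_b)],
        sequences=seqs_a + seqs_b,
        families=["A"] * n_a + ["B"] * n_b,
    )
    truth = AlignmentTruth(
        categories=truth_cats,
        residue_pairs=truth_pairs,
        insertions=list(recipe.planted_insertions),
        tail_length_a=recipe.tail_length_a,
    )
    return aln, truth


def make_tree(n_tips: int, seed: int, height: float = 1.0) -> dendropy.Tree:
    """Seeded Yule (pure-birth) tree with ``n_tips`` leaves, rescaled so every
    root-to-tip distance is exactly ``height`` (ultrametric, binary).

    Lineages split at unit rate; after the last split an extra exponential
    hold time keeps every pendant edge strictly positive.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(int(seed))
    tree = dendropy.Tree()
    root = tree.seed_node
    t = 0.0
    start_time = {root: 0.0}
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        start_time[child] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(rng.integers(len(active)))
        parent.edge.length = t - start_time[parent]
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            start_time[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_tips)
    taxa = dendropy.TaxonNamespace()
    tree.taxon_namespace = taxa
    for i, leaf in enumerate(active):
        leaf.edge.length = t_end - start_time[leaf]
        leaf.taxon = taxa.new_taxon(f"t{i + 1}")
    factor = height / t_end
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def make_forest(
    n_clades: int, n_tips: int, seed: int, height: float = 5.0
) -> list[dendropy.Tree]:
    """Independent Yule clades with globally unique tip labels (c<k>_t<i>).

    Replicate clades — independent draws of the deep gain/loss history —
    are what make the HGT rate identifiable in rate-recovery studies; a
    single tree is a single such draw.
    """
    forest = []
    for k in range(n_clades):
        tree = make_tree(n_tips, seed + 7919 * k, height=height)
        for lf in tree.leaf_node_iter():
            lf.taxon.label = f"c{k}_{lf.taxon.label}"
        forest.append(tree)
    return forest


_TRIPLE_TO_STATES = {
    # one_step bitmask -> (eEF1A, eEF1Ba, EFL) State triple
    s: tuple(
        State.PRESENT if s & g else State.ABSENT for g in ratchet.GENES
    )
    for s in range(8)
}


@dataclass
class TableRecipe:
    """Recipe for a synthetic factor table.

    In ``ratchet_history`` mode, tip states of a ratchet simulation on a
    Yule tree become table rows; a gene lost during the most recent
    ``divergent_fraction`` of tree height is emitted as DIVERGENT rather
    than ABSENT (an ongoing loss still leaves a detectable, degrading
    sequence).  In ``independent_bernoulli`` mode each factor of each taxon
    is present independently with probability ``bernoulli_p`` — the null
    model with no association.
    """

    n_taxa: int = 50
    mode: str = "ratchet_history"  # or "independent_bernoulli"
    model: ratchet.RatchetModel | None = None
    tree_height: float = 1.0
    divergent_fraction: float = 0.0
    bernoulli_p: float | tuple = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ratchet_history", "independent_bernoulli"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 <= self.divergent_fraction <= 1):
            raise ValueError("divergent_fraction must be in [0, 1]")
        if self.mode == "ratchet_history" and self.model is None:
            self.model = ratchet.RatchetModel(loss_rate=0.5, hgt_rate=0.0)


def make_table(recipe: TableRecipe):
    """Generate (FactorTable, history-or-None); deterministic per seed."""
    if recipe.mode == "independent_bernoulli":
        rng = np.random.default_rng(recipe.seed)
        p = recipe.bernoulli_p
        probs = (p, p, p) if np.isscalar(p) else tuple(p)
        draws = rng.random((recipe.n_taxa, 3)) < np.asarray(probs)
        taxa = [f"taxon_{i + 1:04d}" for i in range(recipe.n_taxa)]
        states = [
            tuple(State.PRESENT if d else State.ABSENT for d in row) for row in draws
        ]
        return FactorTable(taxa=taxa, states=states), None

    tree = make_tree(recipe.n_taxa, recipe.seed, height=recipe.tree_height)
    history = ratchet.simulate(recipe.model, tree, seed=recipe.seed)
    cutoff = recipe.tree_height * (1.0 - recipe.divergent_fraction)

    # per tip, the time each gene was (last) lost along its path
    loss_time: dict[str, dict[int, float]] = {
        lf.taxon.label: {} for lf in tree.leaf_node_iter()
    }
    by_branch = history.events_by_branch()

    def walk(node, losses: dict):
        if node.parent_node is not None:
            for ev in by_branch.get(ratchet._branch_id(node), []):
                if ev.kind in ("loss", "lethal"):
                    losses = {**losses, ev.gene: ev.time}
                elif ev.kind == "gain":
                    losses = {k: v for k, v in losses.items() if k != ev.gene}
        if node.is_leaf():
            loss_time[node.taxon.label] = losses
        for child in node.child_nodes():
            walk(child, losses)

    walk(history.tree.seed_node, {})

    taxa, states = [], []
    for label, tip_state in history.tip_states.items():
        if tip_state is None:  # extinct lineage (extinct policy only)
            continue
        triple = []
        for gene in ratchet.GENES:
            if recipe.model.divergence_mode == "two_step":
                lvl = tip_state[ratchet.GENES.index(gene)]
                st = (State.PRESENT, State.DIVERGENT, State.ABSENT)[2 - lvl]
            elif tip_state & gene:
                st = State.PRESENT
            else:
                when = loss_time[label].get(gene)
                recent = when is not None and when >= cutoff
                st = State.DIVERGENT if recent else State.ABSENT
            triple.append(st)
        taxa.append(label)
        states.append(tuple(triple))
    return FactorTable(taxa=taxa, states=states), history
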