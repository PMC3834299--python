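"""Synthetic two-color CGH experiment with known gene-content truth.

The generator emulates a strain-collection genomotyping experiment: probes
are designed from one sequenced reference genome; each test strain (and
optionally one or more outgroup taxa) is co-hybridized against the reference
in technical replicates, and a self-versus-self hybridization of the
reference provides the background/QC baseline.

Gene content evolves by irreversible loss along a random strain tree so
that binary content covaries with phylogeny (a star tree gives the i.i.d.
alternative).  Log-ratios are drawn from class-conditional normals: the
"present" class peaks near 0, the "absent" class is strongly left-shifted,
and a "diverged" class sits in between to exercise the grey zone of the
presence caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrayio import LogRatioTensor, TraitTable, write_intensity_table, write_trait_table
from .errors import ConfigError
from .trees import Node, to_newick

ABSENT, PRESENT, DIVERGED = 0, 1, 2


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce a desk-scale version of the study design: 16
    conspecific strains (one of them the sequenced reference), one outgroup,
    technical triplicates, 10000 probes with a 60% core (a down-scaled stand-in for a ~32k-probe whole-genome design), and class means
    placed ~5 sigma apart (present 0 +/- 0.3, absent -2.5 +/- 0.5 in log2
    units) so the log-ratio histogram is cleanly bimodal.
    """

    n_strains: int = 16              # conspecific strains, reference included
    n_outgroups: int = 1
    n_genes: int = 10000
    core_fraction: float = 0.6
    n_reference_specific: int = 50
    loss_rate_per_branch: float = 0.1   # per unit branch length
    present_mean: float = 0.0
    present_sd: float = 0.3
    absent_mean: float = -2.5
    absent_sd: float = 0.5
    diverged_mean: float = -1.0
    diverged_sd: float = 0.5
    diverged_fraction: float = 0.02
    n_replicates: int = 3
    replicate_sd: float = 0.1
    background_fail_fraction: float = 0.02
    n_trait_genes: int = 20
    trait_group_assignment: dict[str, str] | None = None
    star_tree: bool = False
    outgroup_branch_length: float = 14.0  # ~30% gene-content dissimilarity vs reference
    seed: int = 0

    # --- derived naming ----------------------------------------------------
    @property
    def reference(self) -> str:
        return "ref"

    @property
    def test_strains(self) -> list[str]:
        return [f"s{i:02d}" for i in range(1, self.n_strains)]

    @property
    def outgroups(self) -> list[str]:
        return [f"og{i}" for i in range(1, self.n_outgroups + 1)]

    @property
    def all_strains(self) -> list[str]:
        return [self.reference] + self.test_strains + self.outgroups

    def trait_groups(self) -> dict[str, str]:
        """Strain -> {A, B}; default splits the non-reference strains 7/8."""
        if self.trait_group_assignment is not None:
            return dict(self.trait_group_assignment)
        tests = self.test_strains
        half = (len(tests) + 1) // 2 - 1 if len(tests) % 2 else len(tests) // 2
        half = max(1, half)
        return {s: ("A" if i < half else "B") for i, s in enumerate(tests)}

    def validate(self) -> None:
        n_core = round(self.core_fraction * self.n_genes)
        if not 0 <= self.core_fraction <= 1:
            raise ConfigError("core_fraction must be in [0,1]")
        if n_core + self.n_reference_specific > self.n_genes:
            raise ConfigError("core_fraction*n_genes + n_reference_specific > n_genes")
        if not (self.absent_mean < self.diverged_mean < self.present_mean):
            raise ConfigError("need absent_mean < diverged_mean < present_mean")
        for name in ("present_sd", "absent_sd", "diverged_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.loss_rate_per_branch <= 1:
            raise ConfigError("loss_rate_per_branch must be in [0,1]")
        if self.n_trait_genes > 0:
            groups = self.trait_groups()
            vals = set(groups.values())
            if "A" not in vals or "B" not in vals:
                raise ConfigError("trait pattern impossible: group A or B is empty")
            unknown = set(groups) - set(self.test_strains)
            if unknown:
                raise ConfigError(f"trait assignment names unknown strains: {sorted(unknown)}")
        n_var = self.n_genes - n_core
        if self.n_reference_specific + self.n_trait_genes > n_var:
            raise ConfigError("not enough variable genes for reference-specific + trait genes")


@dataclass
class GeneContentTruth:
    """Ground-truth gene content: codes {0 absent, 1 present, 2 diverged}."""

    gene_ids: list[str]
    strains: list[str]                 # reference first, then tests, then outgroups
    truth: np.ndarray                  # (genes, strains) int8
    tree: Node
    trait_gene_ids: list[str] = field(default_factory=list)
    reference_specific_ids: list[str] = field(default_factory=list)
    reference: str = "ref"
    outgroups: list[str] = field(default_factory=list)

    def presence_bool(self) -> np.ndarray:
        """Truth as binary presence; diverged counts as absent (the array
        cannot separate loss from divergence, so scoring folds them)."""
        return self.truth == PRESENT

    def core_ids(self, scope: list[str] | None = None) -> list[str]:
        scope = scope or [s for s in self.strains if s not in self.outgroups]
        idx = [self.strains.index(s) for s in scope]
        mask = self.presence_bool()[:, idx].all(axis=1)
        return [g for g, m in zip(self.gene_ids, mask) if m]


@dataclass
class ArraySet:
    """Simulated hybridizations: test arrays plus the self-self reference arrays."""

    tensor: LogRatioTensor             # test strains + outgroups
    selfself: LogRatioTensor           # reference vs reference, with raw signals
    low_signal_probe_ids: list[str]    # probes planted below background


def _random_attachment_tree(leaves: list[str], rng: np.random.Generator) -> Node:
    """Sequential random attachment: each new leaf splits a uniformly chosen
    existing edge; pendant lengths are Exp(1)."""
    root = Node()
    first = Node(name=leaves[0], length=float(rng.exponential(1.0)))
    root.children.append(first)
    edges = [first]  # every non-root node stands for the edge above it
    parents = {id(first): root}
    for name in leaves[1:]:
        target = edges[int(rng.integers(len(edges)))]
        parent = parents[id(target)]
        u = float(rng.uniform(0.2, 0.8))
        mid = Node(length=(1 - u) * (target.length or 1.0))
        target.length = u * (target.length or 1.0)
        leaf = Node(name=name, length=float(rng.exponential(1.0)))
        parent.children[parent.children.index(target)] = mid
        mid.children = [target, leaf]
        parents[id(mid)] = parent
        parents[id(target)] = mid
        parents[id(leaf)] = mid
        edges += [mid, leaf]
    return root


def simulate_pangenome(config: SimulationConfig) -> GeneContentTruth:
    """Draw a strain tree and evolve gene content with irreversible loss.

    Core genes are present everywhere; each free variable gene starts
    present at the root and is lost on a branch of length b with
    probability 1 - exp(-loss_rate_per_branch * b); reference-specific and
    trait-gene patterns are then forced.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    strains = config.all_strains
    n_core = round(config.core_fraction * config.n_genes)

    # tree over non-reference strains, reference at the root (its genome is
    # the probe universe, so it keeps everything by construction)
    root = Node()
    root.children.append(Node(name=config.reference, length=0.1))
    if config.star_tree:
        for s in config.test_strains:
            root.children.append(Node(name=s, length=1.0))
    elif config.test_strains:
        sub = _random_attachment_tree(config.test_strains, rng)
        sub.length = 0.1
        root.children.append(sub)
    # outgroup taxa share the long basal branch (they are each other's
    # closest relatives with respect to the ingroup), so with >=2 of them
    # the outgroup side is a genuine internal bipartition of the tree
    if len(config.outgroups) == 1:
        root.children.append(Node(
            name=config.outgroups[0],
            length=config.outgroup_branch_length + float(rng.exponential(1.0))))
    elif config.outgroups:
        anc = Node(length=config.outgroup_branch_length + float(rng.exponential(1.0)))
        for og in config.outgroups:
            anc.children.append(Node(name=og, length=float(rng.exponential(0.5))))
        root.children.append(anc)

    # choose forced gene sets among the variable block
    variable_idx = np.arange(n_core, config.n_genes)
    forced = rng.choice(variable_idx, size=config.n_reference_specific + config.n_trait_genes,
                        replace=False) if len(variable_idx) else np.array([], dtype=int)
    ref_specific_idx = np.sort(forced[:config.n_reference_specific])
    trait_idx = np.sort(forced[config.n_reference_specific:])
    free_idx = np.setdiff1d(variable_idx, forced)

    truth = np.full((config.n_genes, len(strains)), PRESENT, dtype=np.int8)

    # evolve free variable genes down the tree
    n_free = len(free_idx)
    rate = config.loss_rate_per_branch

    def evolve(node: Node, present: np.ndarray) -> None:
        if node.length and rate > 0 and node.name != config.reference:
            p_loss = 1.0 - math.exp(-rate * node.length)
            lost = present & (rng.random(n_free) < p_loss)
            present = present & ~lost
        if node.is_leaf:
            col = strains.index(node.name)
            truth[free_idx[~present], col] = ABSENT
        else:
            for child in node.children:
                evolve(child, present.copy())

    if n_free:
        evolve(root, np.ones(n_free, dtype=bool))

    # relabel a fraction of losses as "diverged" (intermediate signal)
    if config.diverged_fraction > 0:
        lost_cells = truth == ABSENT
        flip = lost_cells & (rng.random(truth.shape) < config.diverged_fraction)
        truth[flip] = DIVERGED

    # forced patterns
    ref_col = strains.index(config.reference)
    non_ref_cols = [i for i in range(len(strains)) if i != ref_col]
    truth[np.ix_(ref_specific_idx, non_ref_cols)] = ABSENT
    truth[ref_specific_idx, ref_col] = PRESENT
    groups = config.trait_groups() if config.n_trait_genes else {}
    for gi in trait_idx:
        for s, lab in groups.items():
            truth[gi, strains.index(s)] = PRESENT if lab == "A" else ABSENT
        for og in config.outgroups:
            truth[gi, strains.index(og)] = ABSENT
        truth[gi, ref_col] = PRESENT
    truth[:, ref_col] = PRESENT  # probes exist in the reference genome

    return GeneContentTruth(
        gene_ids=gene_ids, strains=strains, truth=truth, tree=root,
        trait_gene_ids=[gene_ids[i] for i in trait_idx],
        reference_specific_ids=[gene_ids[i] for i in ref_specific_idx],
        reference=config.reference, outgroups=list(config.outgroups))


def simulate_arrays(truth: GeneContentTruth, config: SimulationConfig) -> ArraySet:
    """Draw log-ratio tensors for all hybridizations, plus self-self arrays.

    Each gene x strain gets a latent class draw Normal(mu_class, sd_class);
    replicates add independent Normal(0, replicate_sd) technical noise.
    Self-self spots are drawn entirely from the present class.  Exactly
    round(background_fail_fraction * n_genes) probes are planted with raw
    channel signals below the background threshold (and uninformative
    log-ratios everywhere), emulating probes that never hybridize.
    """
    config.validate()
    if list(truth.gene_ids) != [f"g{i:05d}" for i in range(config.n_genes)] and \
            len(truth.gene_ids) != config.n_genes:
        raise ConfigError("truth and config disagree on gene count")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    G = len(truth.gene_ids)
    hyb_strains = [s for s in truth.strains if s != truth.reference]
    cols = [truth.strains.index(s) for s in hyb_strains]
    codes = truth.truth[:, cols]

    means = np.choose(codes, [config.absent_mean, config.present_mean, config.diverged_mean])
    sds = np.choose(codes, [config.absent_sd, config.present_sd, config.diverged_sd])
    latent = rng.normal(means, sds)
    values = latent[:, :, None] + rng.normal(
        0.0, config.replicate_sd, size=(G, len(hyb_strains), config.n_replicates))

    # self-self arrays: both channels carry reference DNA -> present class
    ss_latent = rng.normal(config.present_mean, config.present_sd, size=G)
    ss_values = ss_latent[:, None, None] + rng.normal(
        0.0, config.replicate_sd, size=(G, 1, config.n_replicates))

    # plant probes without reliable signal
    n_fail = int(round(config.background_fail_fraction * G))
    fail_idx = np.sort(rng.choice(G, size=n_fail, replace=False)) if n_fail else \
        np.array([], dtype=int)
    if n_fail:
        values[fail_idx] = rng.normal(0.0, 1.5, size=(n_fail, len(hyb_strains),
                                                      config.n_replicates))
        ss_values[fail_idx] = rng.normal(0.0, 1.5, size=(n_fail, 1, config.n_replicates))

    # raw channel signals for the self-self arrays
    fail_mask = np.zeros(G, dtype=bool)
    fail_mask[fail_idx] = True
    rows = []
    for ri in range(config.n_replicates):
        background = rng.normal(100.0, 10.0, size=G).clip(min=1.0)
        good_t = rng.normal(5000.0, 500.0, size=G).clip(min=200.0)
        good_r = rng.normal(5000.0, 500.0, size=G).clip(min=200.0)
        low_t = rng.normal(95.0, 10.0, size=G).clip(min=1.0)
        low_r = rng.normal(95.0, 10.0, size=G).clip(min=1.0)
        rows.append(pd.DataFrame({
            "probe_id": truth.gene_ids,
            "strain": truth.reference,
            "replicate": str(ri + 1),
            "test_signal": np.where(fail_mask, low_t, good_t),
            "ref_signal": np.where(fail_mask, low_r, good_r),
            "background": background,
        }))
    raw = pd.concat(rows, ignore_index=True)

    tensor = LogRatioTensor(list(truth.gene_ids), hyb_strains, values,
                            reference=truth.reference, outgroups=list(truth.outgroups))
    selfself = LogRatioTensor(list(truth.gene_ids), [truth.reference], ss_values,
                              reference=truth.reference, raw=raw)
    return ArraySet(tensor=tensor, selfself=selfself,
                    low_signal_probe_ids=[truth.gene_ids[i] for i in fail_idx])


def simulate_experiment(config: SimulationConfig) -> tuple[GeneContentTruth, ArraySet]:
    """Convenience: truth plus arrays in one call."""
    truth = simulate_pangenome(config)
    return truth, simulate_arrays(truth, config)


def trait_table_from_config(config: SimulationConfig) -> TraitTable:
    return TraitTable(config.trait_groups(), trait_name="planted_trait")


def write_truth(truth: GeneContentTruth, out_dir) -> None:
    """Write truth matrix ({0,1,2} codes), the true tree and the forced gene lists."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    df = pd.DataFrame(truth.truth, index=pd.Index(truth.gene_ids, name="gene_id"),
                      columns=truth.strains)
    df.to_csv(os.path.join(out_dir, "truth_matrix.tsv"), sep="\t", lineterminator="\n")
    with open(os.path.join(out_dir, "true_tree.nwk"), "w", newline="\n") as fh:
        fh.write(to_newick(truth.tree) + "\n")
    for fname, ids in (("trait_genes.txt", truth.trait_gene_ids),
                       ("reference_specific_genes.txt", truth.reference_specific_ids)):
        with open(os.path.join(out_dir, fname), "w", newline="\n") as fh:
            fh.write("".join(g + "\n" for g in ids))


def write_experiment(truth: GeneContentTruth, arrays: ArraySet,
                     config: SimulationConfig, out_dir) -> None:
    import os
    os.makedirs(out_dir, exist_ok=True)
    write_intensity_table(arrays.tensor, os.path.join(out_dir, "intensities.tsv"))
    write_intensity_table(arrays.selfself, os.path.join(out_dir, "selfself.tsv"))
    write_trait_table(trait_table_from_config(config), os.path.join(out_dir, "traits.tsv"))
    write_truth(truth, os.path.join(out_dir, "truth"))
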