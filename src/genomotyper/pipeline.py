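"""End-to-end orchestration: QC -> presence calling -> pan-genome -> tree -> traits.

`run_pipeline` works on in-memory objects and returns every intermediate
artifact; `run_all` is the file-driven wrapper that reads the configured
tables, writes all outputs into the output directory, and serializes a
manifest with every headline count.  Reruns with the same configuration
and inputs are bit-identical: a single root seed drives the bootstrap, and
the manifest carries no timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .arrayio import (LogRatioTensor, TraitTable, read_intensity_table,
                      read_trait_table, write_matrix, write_newick)
from .association import AssociationRule, associate, hits_to_frame
from .calling import PresenceMatrix, call_presence, fit_all_strains
from .errors import ConfigError, GenomotyperError
from .pangenome import PanGenomePartition, partition
from .phylogeny import SupportTree, bootstrap_consensus
from .preprocess import (ProbeQCReport, anova_probe_filter, average_replicates,
                         filter_selfself_background)
from .trees import to_newick

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a reproducible run needs; serialized verbatim into the manifest."""

    intensity_path: str = ""
    selfself_path: str | None = None
    trait_paths: dict[str, str] = field(default_factory=dict)
    out_dir: str = "genomotyper_out"
    reference: str = "ref"
    outgroups: list[str] = field(default_factory=list)
    scope: list[str] | None = None        # core-genome strain scope
    alpha: float = 0.01
    anova_policy: str = "none"
    background_k: float = 3.0
    epp_cutoff: float = 0.95
    metric: str = "hamming"
    bootstrap: int = 1000
    max_fn: int = 1
    max_fp: int = 1
    max_total: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    qc: ProbeQCReport
    presence: PresenceMatrix
    pangenome: PanGenomePartition
    tree: SupportTree
    hits: dict[str, list]
    manifest: dict


def run_pipeline(tensor: LogRatioTensor, selfself: LogRatioTensor | None,
                 traits: dict[str, TraitTable], config: RunConfig) -> PipelineResult:
    """Run every analysis stage on in-memory inputs.

    Any stage failure surfaces as a GenomotyperError naming the stage.
    """
    # --- preprocess -------------------------------------------------------
    if selfself is not None:
        qc = filter_selfself_background(selfself, k=config.background_k)
    else:
        from .preprocess import _empty_report
        qc = _empty_report(tensor.probe_ids, background_k=config.background_k,
                           skipped=True)
    if config.anova_policy != "none":
        qc = qc.merge(anova_probe_filter(tensor, alpha=config.alpha,
                                         policy=config.anova_policy))
    n_input = len(tensor.probe_ids)
    kept_tensor = tensor.subset_probes(qc.kept)
    logger.info("QC: %d -> %d probes kept", n_input, len(kept_tensor.probe_ids))
    rm = average_replicates(kept_tensor)

    # --- presence calling -------------------------------------------------
    fits = fit_all_strains(rm)
    presence = call_presence(fits, rm, cutoff=config.epp_cutoff)

    # --- pan-genome -------------------------------------------------------
    pan = partition(presence, scope=config.scope)

    # --- phylogeny --------------------------------------------------------
    tree = bootstrap_consensus(presence, B=config.bootstrap, seed=config.seed,
                               metric=config.metric)

    # --- trait association ------------------------------------------------
    rule = AssociationRule(config.max_fn, config.max_fp, config.max_total)
    hits = {}
    for name, table in traits.items():
        hits[name] = associate(presence, table, rule=rule)

    manifest = {
        "tool": {"name": "genomotyper", "version": __version__},
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "counts": {
            "n_probes_input": n_input,
            **qc.counts(),
            "present_per_strain": presence.present_counts(),
            "n_core": len(pan.core_genes),
            "n_variable": len(pan.variable_genes),
            "n_reference_specific": len(pan.reference_specific),
            "hits": {name: len(h) for name, h in hits.items()},
        },
        "dissimilarity_pct": {k: round(float(v), 4)
                              for k, v in pan.dissimilarity_pct.items()},
        "fits": {s: f.summary() | {"implied_cutoff": f.implied_cutoff(config.epp_cutoff)}
                 for s, f in sorted(fits.items())},
        "trees": {
            "consensus_newick": to_newick(tree.tree),
            "nj_newick": to_newick(tree.full_tree),
            "bootstrap_replicates": tree.n_replicates,
        },
        "hit_ids": {name: [h.gene_id for h in hs] for name, hs in hits.items()},
    }
    return PipelineResult(qc=qc, presence=presence, pangenome=pan, tree=tree,
                          hits=hits, manifest=manifest)


def write_outputs(result: PipelineResult, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    j = lambda *p: os.path.join(out_dir, *p)
    result.qc.to_frame().to_csv(j("qc_report.tsv"), sep="\t", lineterminator="\n")
    result.presence.to_frame().to_csv(j("presence_matrix.tsv"), sep="\t",
                                      lineterminator="\n")
    result.presence.epp_frame().to_csv(j("epp_matrix.tsv"), sep="\t",
                                       float_format="%.4f", lineterminator="\n")
    write_matrix(result.pangenome.overlap, j("pairwise_overlaps.tsv"))
    for fname, genes in (("core_genes.txt", result.pangenome.core_genes),
                         ("variable_genes.txt", result.pangenome.variable_genes),
                         ("reference_specific_genes.txt",
                          result.pangenome.reference_specific)):
        with open(j(fname), "w", newline="\n") as fh:
            fh.write("".join(g + "\n" for g in genes))
    write_newick(result.tree.tree, j("consensus_tree.nwk"))
    write_newick(result.tree.full_tree, j("nj_tree.nwk"))
    result.tree.support_table().to_csv(j("bipartition_supports.tsv"), sep="\t",
                                       index=False, lineterminator="\n")
    for name, hs in result.hits.items():
        hits_to_frame(hs).to_csv(j(f"trait_hits_{name}.tsv"), sep="\t", index=False,
                                 lineterminator="\n")
    with open(j("manifest.json"), "w", newline="\n") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(config: RunConfig) -> str:
    """File-driven end-to-end run; returns the output directory path."""
    for label, path in [("intensity_path", config.intensity_path),
                        ("selfself_path", config.selfself_path),
                        *[(f"trait:{k}", v) for k, v in config.trait_paths.items()]]:
        if path and not os.path.exists(path):
            raise ConfigError(f"{label} does not exist: {path}")
    tensor = read_intensity_table(config.intensity_path, reference=config.reference,
                                  outgroups=config.outgroups)
    selfself = None
    if config.selfself_path:
        selfself = read_intensity_table(config.selfself_path,
                                        reference=config.reference)
    traits = {}
    for name, path in config.trait_paths.items():
        if not path:
            logger.info("trait table %r empty: association stage skipped", name)
            continue
        traits[name] = read_trait_table(path, trait_name=name)
    result = run_pipeline(tensor, selfself, traits, config)
    write_outputs(result, config.out_dir)
    return config.out_dir
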