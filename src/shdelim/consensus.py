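"""Cross-method comparison of species-hypothesis partitions and majority rule.

Every delimitation method reduces to a :class:`~shdelim.partition.Partition`;
this module assembles them into a per-sequence comparison table (one row per
sequence, one column per method), counts for each candidate species how many
methods recover it as an *exact* cluster, and applies the majority rule: a
candidate is accepted when strictly more than ``cutoff`` methods (default 4 of
7) support it. A lenient support mode, in which a candidate may also be the
union of whole clusters of a method, is available behind a flag for expert
overrides; overrides are always explicit, never silent.

:func:`run_pipeline` chains the whole analysis — distances, OTU clustering at
two thresholds, ASAP, GMYC, PTP, external SH tables, assembly, decisions —
and writes TSV outputs plus a run-metadata log.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .partition import Partition, write_partition_tsv


@dataclass
class CandidateDecision:
    tips: frozenset[str]
    support: int
    decision: str  # "accepted" | "rejected"


@dataclass
class ConsensusTable:
    methods: list[str]
    table: pd.DataFrame                      # index: sequence id; columns: methods
    candidates: list[CandidateDecision] = field(default_factory=list)

    @property
    def n_methods(self) -> int:
        return len(self.methods)


def assemble(partitions: list[Partition]) -> ConsensusTable:
    """Build the per-sequence comparison table from per-method partitions.

    All partitions must cover the identical sequence-id set; a mismatch is an
    error naming the symmetric difference.
    """
    if not partitions:
        raise ValueError("no partitions supplied")
    base = set(partitions[0].assignment)
    for p in partitions[1:]:
        diff = base ^ set(p.assignment)
        if diff:
            raise ValueError(
                f"partition {p.method_id!r} covers a different id set; "
                f"symmetric difference: {sorted(diff)}")
    ids = sorted(base)
    data = {p.method_id: [p.assignment[i] for i in ids] for p in partitions}
    table = pd.DataFrame(data, index=ids, columns=[p.method_id for p in partitions])
    return ConsensusTable([p.method_id for p in partitions], table)


def support_count(candidate_tips, partitions: list[Partition],
                  lenient: bool = False) -> int:
    """Number of methods that recover the candidate as a separate cluster.

    Strict (default): the candidate's tip set equals one cluster of the method
    exactly. Lenient: the candidate is a union of whole clusters of the method.
    """
    tips = frozenset(candidate_tips)
    if not tips:
        raise ValueError("candidate tip set is empty")
    count = 0
    for p in partitions:
        unknown = tips - set(p.assignment)
        if unknown:
            raise ValueError(f"unknown ids for method {p.method_id!r}: {sorted(unknown)}")
        clusters = p.cluster_sets()
        if tips in clusters:
            count += 1
        elif lenient:
            covered = frozenset().union(*(c for c in clusters if c <= tips))
            if covered == tips:
                count += 1
    return count


def majority_decision(support: int, n_methods: int = 7, cutoff: int = 4) -> str:
    """'accepted' iff support > cutoff (strictly more than the cutoff count)."""
    if not (0 <= support <= n_methods):
        raise ValueError(f"support {support} outside [0, {n_methods}]")
    return "accepted" if support > cutoff else "rejected"


def decide(partitions: list[Partition], candidates, cutoff: int = 4,
           lenient: bool = False) -> list[CandidateDecision]:
    """Support count + majority decision for each candidate tip set."""
    out = []
    n = len(partitions)
    for tips in candidates:
        s = support_count(tips, partitions, lenient=lenient)
        out.append(CandidateDecision(frozenset(tips), s, majority_decision(s, n, cutoff)))
    return out


@dataclass
class PipelineConfig:
    """Inputs and knobs for the end-to-end cross-check."""

    fasta: str
    outdir: str
    gmyc_tree: str | None = None        # ultrametric Newick
    ptp_tree: str | None = None         # phylogram Newick
    external_tables: list[str] = field(default_factory=list)  # SH TSVs
    otu_thresholds: tuple[float, ...] = (0.97, 0.985)
    aligned: bool = True                # fasta is an alignment (for distances)
    distance_model: str = "jc69"
    asap_seed: int = 0
    ptp_seed: int = 0
    ptp_generations: int = 100_000
    ptp_burnin: float = 0.1
    cutoff: int = 4
    reference_method: str | None = None  # candidates come from this method's clusters
    lenient_support: bool = False


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every available delimitation method, assemble, and decide.

    Methods degrade gracefully: stages whose inputs are not supplied (e.g. no
    ultrametric tree -> no GMYC) are skipped and the effective method count is
    recorded in the metadata log. Any stage *failure* aborts with the stage
    name and leaves a FAILED marker in the output directory.
    """
    from . import asap, distances, gmyc, otu, ptp, seqio

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    meta: dict = {"version": __version__, "config": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()}}
    try:
        stage = "read sequences"
        records = seqio.read_fasta(config.fasta)
        partitions: list[Partition] = []

        for table in config.external_tables:
            stage = f"external table {table}"
            partitions.extend(seqio.read_partition_table(
                table, known_ids={r.id for r in records}))

        for thr in config.otu_thresholds:
            stage = f"OTU clustering at {thr:g}"
            partitions.append(otu.greedy_cluster(
                records, thr, method_id=f"OTU-{100 * thr:g}"))

        if config.aligned:
            stage = "distance matrix"
            aln = seqio.Alignment(records)
            dmat = distances.pairwise_matrix(aln, model=config.distance_model)
            distances.write_long_tsv(dmat, outdir / "distances.tsv")
            stage = "ASAP partitioning"
            asap_res = asap.asap_partitions(dmat, seed=config.asap_seed)
            asap.write_candidate_table(asap_res, outdir / "asap_candidates.tsv")
            partitions.append(asap_res.best_partition)

        if config.gmyc_tree:
            stage = "GMYC"
            from .trees import read_newick
            ultra = read_newick(config.gmyc_tree)
            fit = gmyc.gmyc_fit(ultra)
            meta["gmyc"] = {"threshold": fit.threshold, "LR": fit.LR,
                            "p_value": fit.p_value, "n_entities": fit.entities.n_clusters}
            partitions.append(fit.entities)

        if config.ptp_tree:
            stage = "PTP"
            from .trees import read_newick
            phylo = read_newick(config.ptp_tree)
            fit_ml = ptp.ptp_ml(phylo, seed=config.ptp_seed)
            fit_bayes = ptp.ptp_bayes(phylo, generations=config.ptp_generations,
                                      burnin_frac=config.ptp_burnin,
                                      seed=config.ptp_seed)
            meta["ptp"] = {"ml_clusters": fit_ml.partition.n_clusters,
                           "bayes_clusters": fit_bayes.partition.n_clusters,
                           "seed": config.ptp_seed}
            partitions.append(ptp.select_fewer(fit_ml, fit_bayes))

        stage = "assemble"
        table = assemble(partitions)
        write_partition_tsv(partitions, outdir / "partitions.tsv")
        table.table.to_csv(outdir / "consensus_table.tsv", sep="\t",
                           index_label="sequence_id")

        stage = "decisions"
        ref = config.reference_method or partitions[0].method_id
        ref_part = next(p for p in partitions if p.method_id == ref)
        decisions = decide(partitions, ref_part.cluster_sets(),
                           cutoff=config.cutoff, lenient=config.lenient_support)
        table.candidates = decisions
        with open(outdir / "decisions.tsv", "w") as fh:
            fh.write("members\tsupport\tdecision\n")
            for d in sorted(decisions, key=lambda d: sorted(d.tips)[0]):
                fh.write(f"{','.join(sorted(d.tips))}\t{d.support}\t{d.decision}\n")

        meta.update({"n_methods": len(partitions),
                     "methods": [p.method_id for p in partitions],
                     "cutoff": config.cutoff,
                     "reference_method": ref,
                     "n_candidates": len(decisions),
                     "n_accepted": sum(d.decision == "accepted" for d in decisions)})
        with open(outdir / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
        return {"partitions": partitions, "table": table,
                "decisions": decisions, "metadata": meta}
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        print(f"pipeline failed at stage {stage!r}: {exc}", file=sys.stderr)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc
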