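"""End-to-end orchestration: subclassing -> TSDS -> coevolution -> network
-> (optional) structure, from a single configuration with one seed.

Every stage writes its tabular output eagerly under the run directory, and
``run_pipeline`` returns (and writes) a JSON-serializable report; the same
configuration and seed produce a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from . import coevolution as coev
from . import network as net
from . import structure as struct
from .motifs import (
    MotifSimilarityMatrix,
    PwmSet,
    merge_motifs,
    read_jaspar,
    read_meme,
    similarity_matrix,
    write_meme,
)
from .msa import AlignedFamily
from .simulate import SyntheticConfig, generate_family
from .subclassing import cluster_subclasses
from .tsds import tsds_permutation_test

log = logging.getLogger("tfcoev")

MAX_NON_CRP_COMPARISON = 500  # cap on non-CRP pairs scored for the motif test


@dataclass
class RunConfig:
    msa_path: str | None = None
    motif_path: str | None = None
    pdb_dir: str | None = None
    blocks: list[tuple[int, int]] | None = None
    top_fraction: float = 0.10
    min_methods: int = 2
    tsds_alpha: float = 0.1
    min_subclass: int = 5
    fcrp_cutoff: float = 10.0
    max_resolution: float = 4.0
    max_gap_frac: float = 0.25
    min_overlap: int = 4
    use_revcomp: bool = True
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 <= self.tsds_alpha <= 1:
            raise ValueError("tsds_alpha must be in [0, 1]")
        if not 0 <= self.max_gap_frac <= 1:
            raise ValueError("max_gap_frac must be in [0, 1]")
        if self.min_methods < 1:
            raise ValueError("min_methods must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if "blocks" in data and data["blocks"] is not None:
            data["blocks"] = [tuple(b) for b in data["blocks"]]
        return cls(**data)


def _read_motifs(path: str) -> PwmSet:
    text = Path(path).read_text()
    if "MEME version" in text:
        return read_meme(path)
    return read_jaspar(path)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_report(report: dict, path: Path) -> None:
    path.write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_json_default) + "\n"
    )


def run_pipeline(
    config: RunConfig,
    outdir,
    msa: AlignedFamily | None = None,
    pwms: PwmSet | None = None,
) -> dict:
    """Run all stages; inputs come from config paths or in-memory objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if msa is None:
        if config.msa_path is None:
            raise ValueError("no MSA provided")
        msa = AlignedFamily.from_fasta(config.msa_path)
    if pwms is None:
        if config.motif_path is None:
            raise ValueError("no motifs provided")
        pwms = _read_motifs(config.motif_path)

    motif_ids = {p.tf_id for p in pwms}
    missing = sorted(set(msa.ids) ^ motif_ids)
    if missing:
        raise ValueError(f"TF ids differ between MSA and motif set: {missing}")

    report: dict = {
        "config": dataclasses.asdict(config),
        "n_tf": msa.n_seq,
        "n_col": msa.n_col,
    }

    # --- motif subclassing -------------------------------------------------
    log.info("stage=subclassing n_tf=%d seed=%d", msa.n_seq, config.seed)
    pwms = sorted(pwms, key=lambda p: msa.ids.index(p.tf_id))
    sims = similarity_matrix(
        pwms, min_overlap=config.min_overlap, use_revcomp=config.use_revcomp
    )
    partition = cluster_subclasses(sims, min_size=config.min_subclass)
    partition.to_frame().to_csv(outdir / "subclasses.tsv", sep="\t", index=False)
    merged = []
    for label in sorted(partition.retained):
        m = merge_motifs(
            pwms,
            partition.members(label),
            min_overlap=config.min_overlap,
            use_revcomp=config.use_revcomp,
        )
        m.tf_id = f"subclass{label}"
        merged.append(m)
    if merged:
        write_meme(merged, outdir / "merged_motifs.meme")
    report["subclassing"] = {
        "k": partition.k,
        "retained_subclasses": sorted(partition.retained),
        "subclass_sizes": {
            str(lab): len(partition.members(lab)) for lab in partition.labels()
        },
        "wss_curve": {str(k): v for k, v in partition.wss_curve.items()},
    }

    # --- TSDS detection ----------------------------------------------------
    tsds_cols: set[int] = set()
    if len(partition.retained) >= 2:
        log.info("stage=tsds n_perm=%d", config.n_perm)
        table = tsds_permutation_test(
            msa,
            partition,
            n_perm=config.n_perm,
            seed=config.seed,
            alpha=config.tsds_alpha,
        )
        table.to_csv(outdir / "tsds.tsv", sep="\t", index=False)
        tsds_cols = set(table.loc[table["is_tsds"], "column"].astype(int))
        report["tsds"] = {
            "n_tsds": len(tsds_cols),
            "tsds_columns": sorted(tsds_cols),
            "n_excluded_invariant": int(table["excluded_invariant"].sum()),
        }
    else:
        report["tsds"] = {
            "skipped": "fewer than two retained subclasses",
            "n_tsds": 0,
            "tsds_columns": [],
        }

    # --- coevolution -------------------------------------------------------
    log.info("stage=coevolution n_col=%d", msa.n_col)
    result = coev.run_coevolution(
        msa,
        max_gap_frac=config.max_gap_frac,
        top_fraction=config.top_fraction,
        min_methods=config.min_methods,
    )
    result.pair_table(msa).to_csv(outdir / "coevolution.tsv", sep="\t", index=False)
    jaccard = coev.method_agreement(result.candidates)
    jaccard.to_csv(outdir / "method_jaccard.tsv", sep="\t")
    report["coevolution"] = {
        "n_scored_columns": int(result.column_mask.sum()),
        "n_crps": len(result.crps),
        "crps": sorted(result.crps),
        "candidate_counts": {m: len(s) for m, s in result.candidates.items()},
        "jaccard": {
            f"{a}|{b}": float(jaccard.loc[a, b])
            for ai, a in enumerate(jaccard.index)
            for b in jaccard.columns[ai + 1 :]
        },
    }

    # --- network -----------------------------------------------------------
    network_report: dict = {}
    rng = np.random.default_rng(config.seed)
    if result.crps:
        log.info("stage=network n_edges=%d", len(result.crps))
        residue_net = net.build_network(result.crps, tsds_cols)
        communities, modularity = net.detect_communities(residue_net)
        net.write_edge_list(residue_net, outdir / "network_edges.tsv")
        net.write_graphml(residue_net, outdir / "network.graphml")
        classification = net.classify_crps(result.crps, tsds_cols)
        blocks = config.blocks
        if blocks is None:
            blocks = net.default_blocks(msa)
        separation = net.separation_and_blocks(result.crps, blocks)
        network_report = {
            "n_communities": len(set(communities.values())),
            "modularity": modularity,
            "crp_fractions": classification["fractions"],
            "crp_counts": classification["counts"],
            "separation": separation,
            "blocks": [list(b) for b in blocks],
        }
        if tsds_cols:
            network_report["tsds_clustering"] = net.tsds_clustering_test(
                residue_net, n_perm=config.n_perm, seed=config.seed
            )
        universe = _pair_universe(result)
        non_crps = sorted(universe - result.crps)
        if len(non_crps) > MAX_NON_CRP_COMPARISON:
            idx = rng.choice(len(non_crps), MAX_NON_CRP_COMPARISON, replace=False)
            non_crps = [non_crps[i] for i in sorted(idx)]
        motif_cmp = net.crp_grouped_motif_similarity(
            result.crps, set(non_crps), msa, sims
        )
        network_report["motif_similarity_comparison"] = {
            k: v for k, v in motif_cmp.items() if not k.endswith("_scores")
        }
    else:
        network_report = {"skipped": "no CRPs"}
    report["network"] = network_report

    # --- structure (optional) ---------------------------------------------
    if config.pdb_dir is not None:
        report["structure"] = _structure_stage(config, msa, result, tsds_cols, outdir)
    else:
        report["structure"] = {"skipped": "no PDB directory supplied"}

    _write_report(report, outdir / "report.json")
    return report


def _pair_universe(result: coev.CoevolutionResult) -> set[tuple[int, int]]:
    cols = np.flatnonzero(result.column_mask)
    return {
        (int(i), int(j))
        for a, i in enumerate(cols)
        for j in cols[a + 1 :]
        if np.isfinite(result.combined[i, j])
    }


def _structure_stage(
    config: RunConfig,
    msa: AlignedFamily,
    result: coev.CoevolutionResult,
    tsds_cols: set[int],
    outdir: Path,
) -> dict:
    pdb_dir = Path(config.pdb_dir)
    complexes = []
    rejected = {}
    for path in sorted(pdb_dir.glob("*.pdb")):
        try:
            complexes.append(
                struct.load_complex(
                    path,
                    max_resolution=config.max_resolution,
                    structure_id=path.stem,
                )
            )
        except struct.ComplexRejectedError as exc:
            rejected[path.stem] = str(exc)
    out: dict = {"n_complexes": len(complexes), "rejected": rejected, "complexes": {}}
    for cx in complexes:
        mapping_by_chain = {}
        for chain in cx.protein_chains():
            try:
                mapping_by_chain[chain] = struct.map_columns_to_residues(
                    msa, msa.seed_id, cx.chain_sequence(chain)
                )
            except struct.MappingError:
                continue
        if not mapping_by_chain:
            out["complexes"][cx.id] = {"skipped": "no chain mapped to seed"}
            continue
        dmap = struct.residue_distances(cx, mapping_by_chain)
        fcrp = struct.classify_fcrps(
            result.crps, dmap, cutoff=config.fcrp_cutoff, tsds=tsds_cols
        )
        if not fcrp["table"].empty:
            fcrp["table"].to_csv(
                outdir / f"fcrp_{cx.id}.tsv", sep="\t", index=False
            )
        crp_d = [
            d for p, d in dmap.pair_distances.items() if p in result.crps
        ]
        non_d = [
            d for p, d in dmap.pair_distances.items() if p not in result.crps
        ]
        spatial = None
        if len(crp_d) >= 2 and len(non_d) >= 2:
            spatial = struct.compare_spatial(crp_d, non_d)
        out["complexes"][cx.id] = {
            "resolution": cx.resolution,
            "n_mapped_columns": len(dmap.dna_distances),
            "fcrp_fraction": fcrp["fcrp_fraction"],
            "n_fcrp_classified": fcrp["n_classified"],
            "n_fcrp_uncovered": fcrp["n_uncovered"],
            "spatial_comparison": spatial,
        }
    return out


def simulate_and_validate(
    syn_config: SyntheticConfig,
    run_config: RunConfig | None = None,
    outdir=None,
) -> dict:
    """Generate a synthetic family, run the pipeline, score the recovery."""
    import tempfile

    if run_config is None:
        run_config = RunConfig(seed=syn_config.seed)
    msa, pwms, truth = generate_family(syn_config)
    if outdir is None:
        tmp = tempfile.TemporaryDirectory()
        outdir = tmp.name
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    msa.to_fasta(outdir / "family.fasta")
    write_meme(pwms, outdir / "motifs.meme")
    truth.to_json(outdir / "truth.json")

    report = run_pipeline(run_config, outdir, msa=msa, pwms=pwms)

    validation: dict = {}
    # subclass recovery (ARI of detected vs planted labels)
    import pandas as pd

    sub = pd.read_csv(outdir / "subclasses.tsv", sep="\t")
    detected_labels = sub.set_index("tf_id")["subclass"].to_dict()
    true_labels = truth.subclass_of
    common = sorted(set(detected_labels) & set(true_labels))
    validation["subclass_ari"] = float(
        adjusted_rand_score(
            [true_labels[t] for t in common], [detected_labels[t] for t in common]
        )
    )
    validation["detected_k"] = report["subclassing"]["k"]
    validation["true_k"] = syn_config.n_subclass

    # TSDS recovery
    called = set(report["tsds"].get("tsds_columns", []))
    if truth.true_tsds:
        hits = called & truth.true_tsds
        validation["tsds_recall"] = len(hits) / len(truth.true_tsds)
        background = set(range(syn_config.n_col)) - truth.true_tsds
        validation["tsds_false_positive_rate"] = (
            len(called & background) / len(background) if background else 0.0
        )
        validation["tsds_precision"] = len(hits) / len(called) if called else None
    elif report["tsds"].get("skipped"):
        validation["tsds_note"] = report["tsds"]["skipped"]

    # planted-pair recovery
    crps = {tuple(p) for p in report["coevolution"]["crps"]}
    if truth.true_pairs:
        hits = crps & truth.true_pairs
        validation["pair_recall"] = len(hits) / len(truth.true_pairs)
        validation["pair_precision"] = len(hits) / len(crps) if crps else None

    report["validation"] = validation
    _write_report(report, outdir / "report.json")
    return report
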