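"""End-to-end orchestration: simulate -> preprocess -> cluster -> classify ->
diversity -> community statistics, with a self-describing run directory."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecostats, hilldiv, io, readprep, simcomm, taxonid
from .otucluster import OtuTable, dereplicate, two_step_cluster
from .taxonid import ClassifyThresholds

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """One JSON-serializable document holding every stage knob."""

    seed: int = 0
    out_dir: str = "amfdiv_run"
    markers: tuple[str, ...] = ("ITS1", "ITS2")
    sim: simcomm.SimConfig = field(default_factory=simcomm.SimConfig)
    min_overlap: int = 16
    max_mismatch_frac: float = 0.25
    min_len: int = 120
    max_ee: float = 1.0
    identity_radius: float = 0.97
    s_min: float = 70.0
    t_species: float = 0.03
    t_genus: float = 0.15
    n_boot: int = 50
    n_perm: int = 999

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        """Rebuild from a (possibly partial) JSON document; missing keys keep defaults."""
        d = json.loads(text)
        sim_d = d.pop("sim", {})
        if "biotope_labels" in sim_d:
            sim_d["biotope_labels"] = tuple(sim_d["biotope_labels"])
        if isinstance(sim_d.get("depth_per_sample"), list):
            sim_d["depth_per_sample"] = list(sim_d["depth_per_sample"])
        sim = simcomm.SimConfig(**sim_d)
        d["markers"] = tuple(d.get("markers", ("ITS1", "ITS2")))
        return cls(sim=sim, **d)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage on a simulated study and write all artifacts.

    Returns a result dict with the in-memory objects of each stage; the run
    directory receives TSV/FASTA/Newick/JSON artifacts plus a manifest with
    the verbatim config and output hashes.  Per-stage read conservation is
    checked and violations raise.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    config.sim.seed = config.seed
    db = simcomm.generate_reference_db(config.sim)
    readset = simcomm.simulate_reads(config.sim, db)
    metadata = simcomm.simulate_metadata(config.sim, readset.amf_reads_per_sample, readset.biotopes)

    io.write_fasta(out / "reference.fasta", [(t.accession, t.sequence) for t in db.all_taxa])
    db.taxonomy_table().to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    readset.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    metadata.to_csv(out / "metadata.tsv", sep="\t")
    io.write_fastq(out / "reads_R1.fastq", [p[0] for p in readset.pairs])
    io.write_fastq(out / "reads_R2.fastq", [p[1] for p in readset.pairs])

    merged, rejected = readprep.preprocess(
        readset.pairs,
        min_overlap=config.min_overlap,
        max_mismatch_frac=config.max_mismatch_frac,
        min_len=config.min_len,
        max_ee=config.max_ee,
    )
    pd.DataFrame(
        [(r.id, r.reason) for r in rejected], columns=["read_id", "reason"]
    ).to_csv(out / "rejected.tsv", sep="\t", index=False)

    taxonomy = {
        row.accession: (row.phylum, row["class"], row.order, row.family, row.genus, row.species)
        for _, row in db.taxonomy_table().iterrows()
    }

    results: dict = {
        "db": db,
        "readset": readset,
        "metadata": metadata,
        "merged": merged,
        "markers": {},
    }
    for marker in config.markers:
        reads = [(r.sample_id, r.sequence) for r in merged if r.region_tag == marker]
        if not reads:
            continue
        dereps = dereplicate(reads)
        refs = db.amf_centroids(marker)
        records, table, discards = two_step_cluster(
            dereps, refs, config.identity_radius,
            samples=readset.sample_ids, marker=marker,
        )
        # read conservation: input reads == assigned + discarded
        n_in = sum(d.total_abundance for d in dereps)
        n_assigned = int(table.counts.values.sum())
        n_discarded = sum(dereps[i].total_abundance for i, _ in discards)
        if n_in != n_assigned + n_discarded:
            raise RuntimeError(
                f"{marker}: read conservation violated ({n_in} != {n_assigned} + {n_discarded})"
            )
        table.to_tsv(out / f"otu_table_{marker}.tsv")
        io.write_fasta(
            out / f"centroids_{marker}.fasta",
            [(f"{r.otu_id};origin={r.origin}", r.centroid_sequence) for r in records],
        )

        ref_index = dict(refs)
        annotations = {}
        for rec in records:
            if rec.origin == "reference":
                annotations[rec.otu_id] = taxonid.Annotation(
                    rec.otu_id, rec.centroid_accession,
                    taxonomy[rec.centroid_accession], 1.0,
                )
            else:
                annotations[rec.otu_id] = taxonid.annotate_best_hit(
                    rec.otu_id, rec.centroid_sequence, refs, taxonomy
                )
        # genus bins on trimmed spacers
        thresholds = ClassifyThresholds(config.s_min, config.t_species, config.t_genus)
        bins: dict[str, dict] = {}
        for rec in records:
            ann = annotations[rec.otu_id]
            if ann.lineage is None:
                continue
            spacer, _ = taxonid.trim_rrna(rec.centroid_sequence, region=marker)
            bins.setdefault(ann.genus, {"otus": {}, "refs": {}, "species": {}})
            bins[ann.genus]["otus"][rec.otu_id] = spacer
        for t in db.amf:
            g = t.genus
            if g in bins:
                bins[g]["refs"][t.accession] = t.spacer(marker)
                bins[g]["species"][t.accession] = t.species
        calls: list[taxonid.TaxonCall] = []
        trees: dict[str, object] = {}
        for g in sorted(bins):
            b = bins[g]
            gcalls, tree = taxonid.classify_genus_bin(
                g, b["otus"], b["refs"], b["species"],
                thresholds, n_boot=config.n_boot, seed=config.seed,
            )
            calls.extend(gcalls)
            if tree is not None:
                trees[g] = tree
                io.write_newick(tree, out / f"tree_{marker}_{g}.nwk")
        unclassified = [
            taxonid.TaxonCall(r.otu_id, "excluded_vt_higher", "unclassified", float("nan"), float("nan"))
            for r in records
            if annotations[r.otu_id].lineage is None
        ]
        calls.extend(unclassified)
        pd.DataFrame(
            [(c.otu_id, c.verdict, c.label, c.support, c.nearest_ref_p_distance) for c in calls],
            columns=["otu_id", "verdict", "label", "support", "nearest_ref_p_distance"],
        ).to_csv(out / f"taxon_calls_{marker}.tsv", sep="\t", index=False)

        summary = taxonid.species_summary(calls, table, readset.biotopes)
        io.write_json(
            {"per_biotope": summary["per_biotope"],
             "venn": {"+".join(k): v for k, v in summary["venn"].items()},
             "endemics": summary["endemics"]},
            out / f"species_summary_{marker}.json",
        )

        # diversity per biotope on species-level counts (excluded VTs dropped)
        keep = {c.otu_id for c in calls if c.verdict in ("species", "vt_species")}
        div_rows = []
        for b in sorted(set(readset.biotopes.values())):
            samples = [s for s in table.counts.index if readset.biotopes[s] == b]
            pooled = table.counts.loc[samples, [c for c in table.counts.columns if c in keep]].sum(axis=0)
            pooled = pooled[pooled > 0]
            if pooled.empty or pooled.sum() < 2:
                continue
            for q in (0, 1, 2):
                try:
                    est = hilldiv.estimate(pooled.to_numpy(), q, n_boot=100, seed=config.seed)
                except ValueError:
                    continue
                div_rows.append((b, q, est.observed, est.asymptotic, est.ci_low, est.ci_high, est.coverage))
        pd.DataFrame(
            div_rows,
            columns=["biotope", "q", "observed", "asymptotic", "ci_low", "ci_high", "coverage"],
        ).to_csv(out / f"hill_{marker}.tsv", sep="\t", index=False)

        # community statistics
        stats_out: dict = {}
        rel = ecostats.tss_normalize(table.counts)
        if rel.shape[0] >= 4 and rel.shape[1] >= 2:
            dist = ecostats.spearman_distance_matrix(rel)
            groups = [readset.biotopes[s] for s in dist.index]
            gc = pd.Series(groups).value_counts()
            if len(gc) >= 2 and (gc >= 2).all():
                an = ecostats.anosim(dist, groups, n_perm=config.n_perm, seed=config.seed)
                stats_out["anosim_r"] = an.r
                stats_out["anosim_p"] = an.p_value
            coords = ecostats.classical_mds(dist.values, k=2)
            pd.DataFrame(coords, index=dist.index, columns=["mds1", "mds2"]).to_csv(
                out / f"mds_{marker}.tsv", sep="\t"
            )
            z = ecostats.ward_clustering(dist.values)
            (out / f"ward_{marker}.nwk").write_text(
                ecostats.dendrogram_newick(z, list(dist.index)) + "\n"
            )
        io.write_json(stats_out, out / f"stats_{marker}.json")

        results["markers"][marker] = {
            "dereps": dereps,
            "records": records,
            "table": table,
            "discards": discards,
            "annotations": annotations,
            "calls": calls,
            "trees": trees,
            "summary": summary,
            "stats": stats_out,
        }

    manifest = {
        "config": json.loads(config.to_json()),
        "outputs": {p.name: _sha(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"},
    }
    io.write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results
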