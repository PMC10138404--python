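"""End-to-end pipeline: simulate → call-mc → annotate → profile/windows/
cluster → dmr → deg → integrate → promoter, with a reproducibility manifest.

Stages communicate only through their declared file outputs under the run
directory.  Each stage records a signature (parameters + SHA-256 of its
input files); re-running with an unchanged signature and existing outputs
skips the stage.  All randomness flows from the single run seed, so a run
repeated with the same configuration and seed produces byte-identical
outputs and manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotation, calling, dmr, integration, io_formats, regions, synthetic

log = logging.getLogger("goosemethyl")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


DEFAULT_THRESHOLDS = {
    "alpha": 0.01,
    "min_depth": 4,
    "dmr": {"min_cpg": 5, "min_delta": 0.25, "max_q": 0.05, "max_gap": 1000},
    "deg": {"min_lfc": 1.0, "max_fdr": 0.05, "pseudocount": 1.0},
    "dmg": {"min_lfc": 1.0, "max_fdr": 0.001, "pseudocount": 0.01},
    "window": 10000,
    "min_sites": 5,
    "flank": 2000,
    "body_bins": 60,
}


def _merge(base: dict, extra: Optional[Mapping]) -> dict:
    out = dict(base)
    for k, v in (extra or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Stage bookkeeping: signatures, checksums, skip-on-unchanged."""

    def __init__(self, out_dir: Path, config: dict, seed: int):
        self.out = out_dir
        self.config = config
        self.seed = seed
        self.manifest: dict = {
            "tool": "goosemethyl",
            "version": __version__,
            "seed": seed,
            "config": config,
            "stages": {},
        }
        prev_path = out_dir / "manifest.json"
        self.previous = {}
        if prev_path.exists():
            try:
                self.previous = json.loads(prev_path.read_text()).get("stages", {})
            except json.JSONDecodeError:
                self.previous = {}
        self._cache: dict[str, pd.DataFrame] = {}

    def rel(self, path: Path) -> str:
        return str(path.relative_to(self.out))

    def stage(self, name: str, inputs: Sequence[Path], outputs: Sequence[Path],
              params: Mapping, fn) -> None:
        signature = {
            "params": params,
            "inputs": {self.rel(p): _sha256(p) for p in sorted(inputs)},
        }
        prev = self.previous.get(name)
        if (
            prev is not None
            and prev.get("signature") == json.loads(json.dumps(signature))
            and all(p.exists() for p in outputs)
        ):
            log.info("stage %s: inputs unchanged, skipping", name)
        else:
            log.info("stage %s: running", name)
            try:
                fn()
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        missing = [p for p in outputs if not p.exists()]
        if missing:
            raise PipelineError(
                f"stage '{name}' failed: missing outputs {[self.rel(p) for p in missing]}"
            )
        self.manifest["stages"][name] = {
            "signature": signature,
            "outputs": {self.rel(p): _sha256(p) for p in sorted(outputs)},
        }

    def read_calls(self, path: Path) -> pd.DataFrame:
        key = str(path)
        if key not in self._cache:
            self._cache[key] = io_formats.read_methylation_table(path)
        return self._cache[key]


def _sim_config(config: dict) -> synthetic.SimulationConfig:
    sim = dict(config.get("simulate") or {})
    known = {f.name for f in dataclasses.fields(synthetic.SimulationConfig)}
    unknown = set(sim) - known
    if unknown:
        raise PipelineError(f"unknown simulate options: {sorted(unknown)}")
    return synthetic.SimulationConfig(**sim)


def run_pipeline(
    config: Union[dict, str, Path],
    out_dir: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
) -> dict:
    """Execute the full pipeline described by ``config``; returns the manifest.

    ``config`` is a mapping (or a YAML file path) with optional keys
    ``simulate`` (synthetic-dataset options), ``thresholds``, ``comparisons``,
    ``promoter``, ``seed`` and ``out``.  When ``simulate`` is absent, an
    ``inputs`` mapping must point at existing genome/genes/sample-sheet/
    calls/FPKM files.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("out") or "goosemethyl_run")
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))
    thresholds = _merge(DEFAULT_THRESHOLDS, config.get("thresholds"))
    simulate = "simulate" in config or "inputs" not in config
    if not simulate:
        inputs = config["inputs"]
        required = ("genome", "genes", "sample_sheet", "calls_dir", "fpkm")
        absent = [k for k in required if k not in inputs]
        if absent:
            raise PipelineError(f"config inputs missing {absent}")
        for key in required:
            if not Path(inputs[key]).exists():
                raise PipelineError(f"input {key} not found: {inputs[key]}")

    run = _Run(out, json.loads(json.dumps(config, default=str)), seed)
    data = out / "data"

    # ---- stage: simulate (or ingest) -------------------------------------
    if simulate:
        sim_cfg = _sim_config(config)
        genome_path = data / "genome.fa"
        genes_path = data / "genes.gff3"
        sheet_path = data / "samples.tsv"
        fpkm_path = data / "fpkm.tsv"
        sample_ids = [r.sample_id for r in synthetic.make_sample_sheet(sim_cfg).itertuples()]
        call_paths = {s: data / "calls" / f"{s}.tsv" for s in sample_ids}
        sim_outputs = [genome_path, genes_path, sheet_path, fpkm_path,
                       *call_paths.values(),
                       data / "truth" / "islands.tsv", data / "truth" / "dmrs.tsv",
                       data / "truth" / "de_genes.tsv", data / "truth" / "genes.tsv",
                       data / "truth" / "promoter.tsv"]

        def do_simulate():
            ds = synthetic.generate_dataset(sim_cfg, seed=seed)
            ds.write(data)

        run.stage(
            "simulate", inputs=[], outputs=sim_outputs,
            params={"seed": seed, "config": dataclasses.asdict(sim_cfg)},
            fn=do_simulate,
        )
    else:
        genome_path = Path(inputs["genome"])
        genes_path = Path(inputs["genes"])
        sheet_path = Path(inputs["sample_sheet"])
        fpkm_path = Path(inputs["fpkm"])
        sheet_tmp = io_formats.read_sample_sheet(sheet_path)
        call_paths = {
            r.sample_id: Path(inputs["calls_dir"]) / f"{r.sample_id}.tsv"
            for r in sheet_tmp.itertuples()
        }

    genome = io_formats.read_fasta(genome_path)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    genes = io_formats.read_gene_models(genes_path)
    sheet = io_formats.read_sample_sheet(sheet_path)
    fpkm = io_formats.read_fpkm(fpkm_path)
    gene_regions = annotation.derive_all_gene_regions(genes, chrom_lengths=chrom_lengths)

    breeds = sorted(sheet["breed"].unique())
    stages = list(dict.fromkeys(sheet["stage"]))
    comparisons = config.get("comparisons")
    if comparisons is None:
        # default: later-listed breed vs first (STE-like vs WZE-like) per stage
        a_breed, b_breed = breeds[-1], breeds[0]
        if "STE" in breeds and "WZE" in breeds:
            a_breed, b_breed = "STE", "WZE"
        comparisons = [
            {"group_a": {"breed": a_breed, "stage": st},
             "group_b": {"breed": b_breed, "stage": st}}
            for st in stages
        ]

    def group_samples(spec: Mapping) -> list[str]:
        return io_formats.require_replicates(sheet, spec["breed"], spec["stage"])

    def group_label(spec: Mapping) -> str:
        return f"{spec['breed']}_{spec['stage']}"

    min_depth = thresholds["min_depth"]

    # ---- stage: call-mc ---------------------------------------------------
    mc_dir = out / "mc"
    mc_paths = {s: mc_dir / f"{s}.tsv" for s in call_paths}
    fp_path = mc_dir / "false_positive_rates.tsv"

    def do_call_mc():
        mc_dir.mkdir(exist_ok=True)
        fp_rows = []
        for s, path in call_paths.items():
            calls = run.read_calls(path)
            fp = calling.estimate_false_positive_rate(calls)
            status = calling.call_mc_table(
                calls, fp, alpha=thresholds["alpha"], min_depth=min_depth
            )
            status.to_csv(mc_paths[s], sep="\t", index=False, float_format="%.6g")
            fp_rows.append(
                {"sample_id": s, "n_mchg": fp.n_mchg, "n_mchh": fp.n_mchh,
                 "n_depth": fp.n_depth, "rate": fp.rate}
            )
            log.info("sample %s: false-positive rate %.4f%%", s, fp.percent)
        pd.DataFrame(fp_rows).to_csv(fp_path, sep="\t", index=False, float_format="%.8g")

    run.stage(
        "call_mc", inputs=list(call_paths.values()),
        outputs=[*mc_paths.values(), fp_path],
        params={"alpha": thresholds["alpha"], "min_depth": min_depth},
        fn=do_call_mc,
    )

    # ---- stage: annotate --------------------------------------------------
    ann_dir = out / "annotation"
    ann_outputs = [ann_dir / "islands.bed", ann_dir / "islands.tsv",
                   ann_dir / "shores.bed", ann_dir / "shelves.bed",
                   ann_dir / "gene_regions.bed"]

    def do_annotate():
        ann_dir.mkdir(exist_ok=True)
        islands = annotation.detect_cpg_islands(genome)
        islands.to_csv(ann_dir / "islands.tsv", sep="\t", index=False, float_format="%.6g")
        bed = islands.assign(
            name=[f"island_{i + 1}" for i in range(len(islands))],
            score=np.clip(islands["obs_exp_cpg"], 0, 1) if len(islands) else [],
        )
        io_formats.write_bed(bed, ann_dir / "islands.bed")
        flanks = annotation.derive_shores_shelves(islands, chrom_lengths, genome=genome)
        for kind, fname in (("shore", "shores.bed"), ("shelf", "shelves.bed")):
            sub = flanks[flanks["kind"] == kind]
            bed = sub.assign(
                name=[f"{kind}_{i + 1}" for i in range(len(sub))],
                score=np.clip(sub["obs_exp_cpg"].fillna(0), 0, 1) if len(sub) else [],
            )
            io_formats.write_bed(bed, ann_dir / fname)
        rows = []
        for gr in gene_regions:
            for region_type in ("upstream2k", "body", "downstream2k"):
                s, e = gr.region(region_type)
                if s < e:
                    rows.append({"chrom": gr.chrom, "start": s, "end": e,
                                 "name": f"{gr.gene_id}:{region_type}", "score": 0.0})
        io_formats.write_bed(pd.DataFrame(rows), ann_dir / "gene_regions.bed")

    run.stage(
        "annotate", inputs=[genome_path, genes_path], outputs=ann_outputs,
        params={"flank": thresholds["flank"]}, fn=do_annotate,
    )

    # ---- stage: profile (per breed/stage group) ---------------------------
    prof_dir = out / "profiles"
    groups = sorted({(r.breed, r.stage) for r in sheet.itertuples()})
    prof_paths = {g: prof_dir / f"{g[0]}_{g[1]}.tsv" for g in groups}
    levels_path = prof_dir / "region_levels.tsv"

    def do_profile():
        prof_dir.mkdir(exist_ok=True)
        level_rows = []
        for breed, stage in groups:
            ids = list(sheet.loc[(sheet.breed == breed) & (sheet.stage == stage), "sample_id"])
            pooled = pd.concat([run.read_calls(call_paths[s]) for s in ids], ignore_index=True)
            prof = regions.metagene_profile(
                pooled, genes, flank=thresholds["flank"],
                body_bins=thresholds["body_bins"], min_depth=min_depth,
            )
            prof.to_frame().to_csv(
                prof_paths[(breed, stage)], sep="\t", index=False, float_format="%.6g"
            )
            for s in ids:
                calls = run.read_calls(call_paths[s])
                level_rows.append(
                    {"sample_id": s, "breed": breed, "stage": stage,
                     "region": "genome", "level": regions.pooled_level(calls, min_depth=min_depth)}
                )
                for region_type in ("upstream2k", "body", "downstream2k"):
                    pooled_region = regions.pooled_interval_level(
                        calls,
                        [(gr.chrom, *gr.region(region_type)) for gr in gene_regions],
                        min_depth=min_depth,
                    )
                    level_rows.append(
                        {"sample_id": s, "breed": breed, "stage": stage,
                         "region": region_type, "level": pooled_region.level}
                    )
        pd.DataFrame(level_rows).to_csv(levels_path, sep="\t", index=False, float_format="%.6g")

    run.stage(
        "profile", inputs=[*call_paths.values(), genes_path],
        outputs=[*prof_paths.values(), levels_path],
        params={"flank": thresholds["flank"], "body_bins": thresholds["body_bins"],
                "min_depth": min_depth},
        fn=do_profile,
    )

    # ---- stage: windows + cluster ----------------------------------------
    win_path = out / "windows" / "matrix.tsv"
    clus_dir = out / "cluster"
    clus_outputs = [clus_dir / "dendrogram.nwk", clus_dir / "pca_scores.tsv"]

    def do_windows():
        win_path.parent.mkdir(exist_ok=True)
        calls_by_sample = {s: run.read_calls(p) for s, p in call_paths.items()}
        mat = regions.window_matrix(
            calls_by_sample, chrom_lengths,
            window=thresholds["window"], min_sites=thresholds["min_sites"],
            min_depth=min_depth,
        )
        mat.to_csv(win_path, sep="\t", float_format="%.6g")

    run.stage(
        "windows", inputs=list(call_paths.values()), outputs=[win_path],
        params={"window": thresholds["window"], "min_sites": thresholds["min_sites"],
                "min_depth": min_depth},
        fn=do_windows,
    )

    def do_cluster():
        clus_dir.mkdir(exist_ok=True)
        mat = pd.read_csv(win_path, sep="\t", index_col=[0, 1])
        result = regions.cluster_and_ordinate(mat)
        (clus_dir / "dendrogram.nwk").write_text(
            regions.linkage_to_newick(result.linkage, list(result.samples)) + "\n"
        )
        result.pca_scores.to_csv(clus_dir / "pca_scores.tsv", sep="\t",
                                 index_label="sample_id", float_format="%.6g")

    run.stage("cluster", inputs=[win_path], outputs=clus_outputs, params={}, fn=do_cluster)

    # ---- stages: dmr / deg / integrate per comparison ---------------------
    dmr_thr = thresholds["dmr"]
    deg_thr = thresholds["deg"]
    dmg_thr = thresholds["dmg"]
    int_dir = out / "integrate"

    for comp in comparisons:
        a_spec, b_spec = comp["group_a"], comp["group_b"]
        tag = f"{group_label(a_spec)}_vs_{group_label(b_spec)}"
        ids_a, ids_b = group_samples(a_spec), group_samples(b_spec)
        paths_a = [call_paths[s] for s in ids_a]
        paths_b = [call_paths[s] for s in ids_b]
        dmr_dir = out / "dmr"
        dmr_outputs = [dmr_dir / f"{tag}.tsv", dmr_dir / f"{tag}.bed",
                       dmr_dir / f"{tag}_genes.tsv", dmr_dir / f"{tag}_dmgs.tsv"]

        def do_dmr(paths_a=paths_a, paths_b=paths_b, tag=tag,
                   a_label=group_label(a_spec), b_label=group_label(b_spec)):
            dmr_dir.mkdir(exist_ok=True)
            calls_a = [run.read_calls(p) for p in paths_a]
            calls_b = [run.read_calls(p) for p in paths_b]
            dmrs = dmr.call_dmrs(
                calls_a, calls_b, min_cpg=dmr_thr["min_cpg"],
                min_delta=dmr_thr["min_delta"], max_q=dmr_thr["max_q"],
                max_gap=dmr_thr["max_gap"], min_depth=min_depth,
            )
            violations = dmr.validate_dmrs(
                dmrs, calls_a, calls_b, min_cpg=dmr_thr["min_cpg"],
                min_delta=dmr_thr["min_delta"], max_q=dmr_thr["max_q"],
                max_gap=dmr_thr["max_gap"], min_depth=min_depth,
            )
            if violations:
                raise PipelineError(f"DMR validator: {violations}")
            dmrs.to_csv(dmr_dir / f"{tag}.tsv", sep="\t", index=False, float_format="%.6g")
            bed = dmrs.assign(
                name=[f"dmr_{i + 1}_{d}" for i, d in enumerate(dmrs["direction"])],
                score=dmrs["delta"].abs(),
            )
            io_formats.write_bed(bed, dmr_dir / f"{tag}.bed")
            dmr_genes = dmr.assign_dmr_genes(dmrs, gene_regions)
            dmr_genes.attrs["group_a"] = a_label
            dmr_genes.attrs["group_b"] = b_label
            dmr_genes.to_csv(dmr_dir / f"{tag}_genes.tsv", sep="\t", index=False,
                             float_format="%.6g")
            dmgs = dmr.call_dmgs(
                calls_a, calls_b, gene_regions,
                pseudocount=dmg_thr["pseudocount"], min_lfc=dmg_thr["min_lfc"],
                max_fdr=dmg_thr["max_fdr"], min_depth=min_depth,
            )
            dmgs.to_csv(dmr_dir / f"{tag}_dmgs.tsv", sep="\t", index=False,
                        float_format="%.6g")

        run.stage(
            f"dmr:{tag}", inputs=[*paths_a, *paths_b, genes_path],
            outputs=dmr_outputs, params={"thresholds": dmr_thr, "dmg": dmg_thr},
            fn=do_dmr,
        )

        deg_path = out / "deg" / f"{tag}.tsv"

        def do_deg(ids_a=ids_a, ids_b=ids_b, deg_path=deg_path,
                   a_label=group_label(a_spec), b_label=group_label(b_spec)):
            deg_path.parent.mkdir(exist_ok=True)
            degs = integration.call_degs(
                fpkm[ids_a], fpkm[ids_b],
                pseudocount=deg_thr["pseudocount"], min_lfc=deg_thr["min_lfc"],
                max_fdr=deg_thr["max_fdr"], group_a=a_label, group_b=b_label,
                return_all=True,
            )
            degs.to_csv(deg_path, sep="\t", float_format="%.6g")

        run.stage(
            f"deg:{tag}", inputs=[fpkm_path, sheet_path], outputs=[deg_path],
            params={"thresholds": deg_thr}, fn=do_deg,
        )

        int_outputs = [int_dir / f"{tag}_records.tsv", int_dir / f"{tag}_counts.tsv"]

        def do_integrate(tag=tag, deg_path=deg_path,
                         a_label=group_label(a_spec), b_label=group_label(b_spec)):
            int_dir.mkdir(exist_ok=True)
            degs_all = pd.read_csv(deg_path, sep="\t", index_col="gene_id")
            degs = degs_all[degs_all["is_deg"]]
            degs.attrs["group_a"] = a_label
            degs.attrs["group_b"] = b_label
            dmr_genes = pd.read_csv(out / "dmr" / f"{tag}_genes.tsv", sep="\t")
            dmr_genes.attrs["group_a"] = a_label
            dmr_genes.attrs["group_b"] = b_label
            records, counts = integration.intersect_and_classify(degs, dmr_genes)
            records.to_csv(int_dir / f"{tag}_records.tsv", sep="\t", index=False)
            counts.to_csv(int_dir / f"{tag}_counts.tsv", sep="\t", index=False)

        run.stage(
            f"integrate:{tag}",
            inputs=[deg_path, out / "dmr" / f"{tag}_genes.tsv"],
            outputs=int_outputs, params={}, fn=do_integrate,
        )

    # ---- stage: promoter per-site comparison ------------------------------
    prom_cfg = dict(config.get("promoter") or {})
    prom_gene_id = prom_cfg.get("gene", "auto")
    if prom_gene_id == "auto" and simulate:
        prom_truth = pd.read_csv(data / "truth" / "promoter.tsv", sep="\t")
        prom_gene_id = str(prom_truth["gene_id"].iloc[0])
    if prom_gene_id and prom_gene_id != "auto":
        gene = next((g for g in genes if g.gene_id == prom_gene_id), None)
        if gene is None:
            raise PipelineError(f"promoter gene {prom_gene_id!r} not in gene models")
        prom_dir = out / "promoter"
        prom_outputs = []
        for comp in comparisons:
            a_spec, b_spec = comp["group_a"], comp["group_b"]
            tag = f"{group_label(a_spec)}_vs_{group_label(b_spec)}"
            path = prom_dir / f"{tag}.tsv"
            prom_outputs.append(path)

            def do_prom(a_spec=a_spec, b_spec=b_spec, path=path):
                prom_dir.mkdir(exist_ok=True)
                calls_a = [run.read_calls(call_paths[s]) for s in group_samples(a_spec)]
                calls_b = [run.read_calls(call_paths[s]) for s in group_samples(b_spec)]
                tab = integration.promoter_site_comparison(
                    calls_a, calls_b, gene,
                    from_offset=int(prom_cfg.get("from", -723)),
                    to_offset=int(prom_cfg.get("to", -480)),
                    min_depth=min_depth,
                )
                tab.to_csv(path, sep="\t", index=False, float_format="%.6g")

            run.stage(
                f"promoter:{tag}",
                inputs=[call_paths[s] for s in group_samples(a_spec) + group_samples(b_spec)],
                outputs=[path],
                params={"gene": prom_gene_id,
                        "from": prom_cfg.get("from", -723),
                        "to": prom_cfg.get("to", -480)},
                fn=do_prom,
            )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(run.manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return run.manifest
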