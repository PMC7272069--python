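"""Pipeline orchestration from a single YAML/JSON run configuration.

Stages run in dependency order (digest -> tags -> count -> call ->
annotate -> validate); every output is listed in a manifest JSON with input
checksums and the run seed, and a rerun with identical config and inputs
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import caller, context_stats, digest, io_formats, tagbuilder, wgbs

log = logging.getLogger("msdart")


@dataclass
class RunConfig:
    genome: str
    alignments: list[dict]  # {tissue, replicate, library, path}
    output_dir: str
    features: str | None = None
    features_kind: str | None = None
    cytosine_report: str | None = None
    non_conversion_rate: float = 0.005
    tissue: str | None = None  # tissue to call; default: first listed
    seed: int = 0
    caller_params: dict = field(default_factory=dict)
    overlap_correction: str = "nested"  # nested | off
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        missing = []
        if not Path(self.genome).exists():
            missing.append(self.genome)
        seen = {}
        for a in self.alignments:
            for key in ("tissue", "replicate", "library", "path"):
                if key not in a:
                    raise ValueError(f"alignment entry missing {key!r}: {a}")
            if not Path(a["path"]).exists():
                missing.append(a["path"])
            seen.setdefault((a["tissue"], a["replicate"]), set()).add(a["library"])
        for path in (self.features, self.cytosine_report):
            if path and not Path(path).exists():
                missing.append(path)
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        for sample, libs in seen.items():
            if libs != {"MspI", "HpaII"}:
                raise ValueError(
                    f"sample {sample} must map to exactly one MspI and one HpaII "
                    f"alignment file; got {sorted(libs)}"
                )


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the stage sequence; returns the manifest dict."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "inputs": {config.genome: _sha256(config.genome)},
        "outputs": [],
        "status": "running",
    }
    for a in config.alignments:
        manifest["inputs"][a["path"]] = _sha256(a["path"])

    def emit(name: str):
        manifest["outputs"].append(str(outdir / name))
        return outdir / name

    try:
        log.info("[digest] scanning restriction sites")
        genome = io_formats.load_genome(config.genome)
        site_map = digest.find_sites(genome, [digest.PSTI, digest.MSPI])
        io_formats.write_bed(
            sorted(
                (chrom, int(p), int(p) + len(enz.recognition), enz.name)
                for chrom in site_map.chromosomes
                for enz in (digest.PSTI, digest.MSPI)
                for p in site_map.positions(chrom, enz.name)
            ),
            emit("sites.bed"),
            header="restriction recognition sites",
        )

        log.info("[tags] deriving MSD-tags from alignments")
        alignments = []
        for a in config.alignments:
            alignments.extend(
                io_formats.load_alignments(
                    a["path"], (a["tissue"], a["replicate"]), a["library"],
                    genome=genome,
                )
            )
        alignments.sort(key=lambda r: (r.chrom, r.start, r.end))
        derivation = tagbuilder.derive_observed_tags(alignments, site_map)
        io_formats.write_bed(
            tagbuilder.tags_to_bed(derivation.tags), emit("tags.bed"),
            header="MSD-tags (name = tag_id|site_id)",
        )

        log.info("[count] counting reads per tag")
        counts = tagbuilder.count_reads(alignments, derivation.tags, site_map)
        if config.overlap_correction == "nested":
            counts = tagbuilder.correct_overlap_counts(counts, derivation.tags)
        flat = counts.data.copy()
        flat.columns = ["|".join(c) for c in flat.columns]
        with open(emit("counts.tsv"), "w") as fh:
            fh.write("# MSD-tag counts per (tissue|replicate|library)\n")
            flat.to_csv(fh, sep="\t", index_label="tag_id")

        log.info("[call] dual NB methylation calling")
        params = caller.CallerParams(**config.caller_params)
        tissue = config.tissue or config.alignments[0]["tissue"]
        filtered, _status = caller.filter_tags(counts, params)
        tag_site = {t.tag_id: t.msd_site_id for t in derivation.tags}
        calls = caller.call_methylation(filtered, params, tissue, tag_site=tag_site)
        with open(emit("calls.tsv"), "w") as fh:
            fh.write("# per-tag methylation calls\n")
            caller.calls_to_frame(calls).to_csv(fh, sep="\t", index=False)

        if config.features:
            log.info("[annotate] genomic-context classification")
            features = io_formats.load_features(config.features,
                                                feature_kind=config.features_kind)
            annotations = context_stats.classify_context(
                derivation.sites, features, genome.lengths
            )
            with open(emit("context.tsv"), "w") as fh:
                fh.write("# site_id\tcategory\tnearest_gene_bp\tnearest_te_bp\tgene_id\tte_id\n")
                for a in annotations:
                    fh.write(
                        f"{a.site_id}\t{a.category}\t{a.nearest_gene_distance}\t"
                        f"{a.nearest_te_distance}\t{a.gene_id or '.'}\t{a.te_id or '.'}\n"
                    )

        if config.cytosine_report:
            log.info("[validate] WGBS concordance")
            records = io_formats.load_cytosine_report(config.cytosine_report)
            cyt_calls = wgbs.call_cytosines(records, config.non_conversion_rate)
            states = wgbs.classify_sites(derivation.sites, cyt_calls)
            with open(emit("states.tsv"), "w") as fh:
                fh.write("# site_id\twgbs_state\n")
                for s in states:
                    fh.write(f"{s.site_id}\t{s.state}\n")
            report = wgbs.concordance(calls, states)
            with open(emit("concordance.tsv"), "w") as fh:
                fh.write("# n_msd_called\tn_covered_by_wgbs\tn_confirmed\tprecision\n")
                prec = "" if report.precision is None else f"{report.precision:.4f}"
                fh.write(
                    f"{report.n_msd_called}\t{report.n_covered_by_wgbs}\t"
                    f"{report.n_confirmed}\t{prec}\n"
                )
        manifest["status"] = "completed"
    except Exception as exc:  # partial outputs retained, failure point recorded
        manifest["status"] = f"failed: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
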