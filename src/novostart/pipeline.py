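"""End-to-end orchestration of the four analysis stages.

``run_all`` executes start-gain SNV discovery, the human-specific start
codon scan, ribosome-occupancy profiling, and the branch-model Ka/Ks tests
over one set of input files, writing per-stage tables, a machine-readable
manifest (parameters, seed, output hashes) and a summary of the headline
quantities. Stage outputs are pure functions of (inputs, config, seed);
rerunning with the same seed reproduces the manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import codon_evolution as ce
from . import io as nio
from . import riboprofile as rp
from . import species_specific as ss
from . import startgain as sg

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds (study defaults) and stage toggles for one run."""

    human_fasta: str = ""
    chimp_fasta: str = ""
    gorilla_fasta: str = ""
    orangutan_fasta: str = ""
    human_gff: str = ""
    chimp_gff: str = ""
    vcf: str = ""
    maf_chimp: str = ""
    maf_gorilla: str = ""
    maf_orangutan: str = ""
    ribo_dir: str = ""
    human_ribo_samples: list[str] = field(default_factory=list)
    chimp_ribo_samples: list[str] = field(default_factory=list)
    blacklist_bed: str = ""
    out_dir: str = "results"
    # thresholds, with the study's values as defaults
    min_codons: int = 5
    min_carriers: int = 3
    nmd_distance_nt: int = 50
    concat_min_len_nt: int = 15
    metagene_window: int = 10
    seed: int = 0
    run_startgain: bool = True
    run_species: bool = True
    run_ribo: bool = True
    run_kaks: bool = True

    @classmethod
    def from_fixture(cls, paths: dict, truth: dict, out_dir: str, seed: int = 0) -> "RunConfig":
        return cls(
            human_fasta=paths["fasta_human"],
            chimp_fasta=paths["fasta_chimpanzee"],
            gorilla_fasta=paths["fasta_gorilla"],
            orangutan_fasta=paths["fasta_orangutan"],
            human_gff=paths["gff_human"],
            chimp_gff=paths["gff_chimp"],
            vcf=paths["vcf"],
            maf_chimp=paths["maf_chimpanzee"],
            maf_gorilla=paths["maf_gorilla"],
            maf_orangutan=paths["maf_orangutan"],
            ribo_dir=os.path.dirname(paths[f"sam_{truth['ribo_samples'][0]}"]),
            human_ribo_samples=list(truth["ribo_samples"]),
            chimp_ribo_samples=list(truth["chimp_samples"]),
            blacklist_bed=paths["blacklist"],
            out_dir=out_dir,
            seed=seed,
        )


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run the enabled stages; return the summary dict (also written to
    ``out_dir/summary.json`` beside the per-stage tables and manifest)."""
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: list[str] = []
    summary: dict = {}

    human_genome = nio.read_genome(config.human_fasta, "human")
    human_transcripts = nio.read_gff3(config.human_gff, human_genome)
    human_by_id = {t.transcript_id: t for t in human_transcripts}
    snvs = nio.read_vcf(config.vcf) if config.vcf else []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(config.out_dir, name)
        nio.write_tsv(df, path)
        outputs.append(path)

    sg_calls: list[sg.StartGainCall] = []
    sg_kept: list[sg.StartGainCall] = []
    if config.run_startgain:
        sg_calls = sg.call_all(snvs, human_transcripts, human_genome)
        sg_kept = sg.filter_for_occupancy(sg_calls, config.min_codons, config.min_carriers)
        tables = sg.population_summary(sg_calls)
        _write(sg.calls_table(sg_calls), "startgain_calls.tsv")
        _write(sg.calls_table(sg_kept), "startgain_kept.tsv")
        _write(tables["per_individual"], "startgain_per_individual.tsv")
        _write(tables["length_quantiles"], "startgain_length_quantiles.tsv")
        nmd_rows = []
        for c in sg.dedup_by_snv(sg_calls):
            t = human_by_id[c.transcript_id]
            n = sg.nmd_classify(t, config.nmd_distance_nt)
            nmd_rows.append(
                {
                    "transcript_id": n.transcript_id,
                    "stop_codon_tpos": n.stop_codon_tpos,
                    "last_junction_tpos": n.last_junction_tpos,
                    "distance_nt": n.distance_nt,
                    "nmd_predicted": n.nmd_predicted,
                    "single_exon": n.single_exon,
                }
            )
        _write(pd.DataFrame(nmd_rows), "startgain_nmd.tsv")
        per_ind = tables["per_individual"]["n_novel_start_codons"]
        summary["startgain"] = {
            "n_snvs_in_vcf": len(snvs),
            "n_calls": len(sg.dedup_by_snv(sg_calls)),
            "n_kept_for_occupancy": len(sg.dedup_by_snv(sg_kept)),
            "mean_burden_per_individual": float(per_ind.mean()) if len(per_ind) else 0.0,
            "median_novel_cds_len_nt": float(
                np.median([c.novel_cds_len_nt for c in sg.dedup_by_snv(sg_calls)])
            )
            if sg_calls
            else None,
            "n_nmd_predicted": int(sum(r["nmd_predicted"] for r in nmd_rows)),
        }

    hss_calls: list[ss.HssCall] = []
    panel = pd.DataFrame()
    chimp_by_id: dict = {}
    lifts: dict[str, ss.LiftMap] = {}
    if config.run_species:
        chimp_genome = nio.read_genome(config.chimp_fasta, "chimpanzee")
        chimp_transcripts = nio.read_gff3(config.chimp_gff, chimp_genome)
        chimp_by_id = {t.transcript_id: t for t in chimp_transcripts}
        blocks = {
            "chimpanzee": nio.read_maf(config.maf_chimp),
            "gorilla": nio.read_maf(config.maf_gorilla),
            "orangutan": nio.read_maf(config.maf_orangutan),
        }
        one2one = {sp: ss.filter_one_to_one(b) for sp, b in blocks.items()}
        lifts = {sp: ss.LiftMap(b) for sp, b in one2one.items()}
        sites = ss.find_divergent_sites(
            one2one["chimpanzee"],
            human_genome,
            chimp_genome,
            outgroup_lifts={"gorilla": lifts["gorilla"], "orangutan": lifts["orangutan"]},
        )
        population = {(r.contig, r.pos): r for r in snvs}
        hss_calls, reasons = ss.call_all(
            sites, human_transcripts, chimp_transcripts, population, lifts["chimpanzee"]
        )
        for c in hss_calls:
            ss.flag_cug_origin(c, human_by_id, lifts["chimpanzee"])
        panel = ss.hssc_site_panel(
            hss_calls, human_by_id, chimp_by_id, lifts["chimpanzee"], config.min_codons
        )
        _write(panel, "hssc_panel.tsv")
        reason_df = pd.DataFrame(
            [{"site": k, "reason": v} for k, v in sorted(reasons.items())]
        )
        _write(reason_df, "hssc_site_reasons.tsv")
        summary["species"] = {
            "n_divergent_sites": len(sites),
            "n_hssc": len(hss_calls),
            "n_analyzable": int(panel["analyzable"].sum()) if len(panel) else 0,
            "n_cug_origin": int(sum(bool(c.cug_origin) for c in hss_calls)),
            "n_non_cug_analyzable": int(
                ((panel["analyzable"]) & (~panel["cug_origin"].astype(bool))).sum()
            )
            if len(panel)
            else 0,
            "median_novel_cds_len_nt": float(panel["novel_cds_len_nt"].median())
            if len(panel)
            else None,
        }

    if config.run_ribo:
        blacklist = nio.read_bed_intervals(config.blacklist_bed) if config.blacklist_bed else None
        human_tracks = []
        for sid in config.human_ribo_samples:
            reads = nio.read_sam(os.path.join(config.ribo_dir, f"{sid}.sam"), sid, blacklist)
            human_tracks.append(rp.build_rpm_track(rp.filter_reads(reads), sid))
        chimp_tracks = []
        for sid in config.chimp_ribo_samples:
            reads = nio.read_sam(os.path.join(config.ribo_dir, f"{sid}.sam"), sid, blacklist)
            chimp_tracks.append(rp.build_rpm_track(rp.filter_reads(reads), sid))

        summary["ribo"] = {}
        # carrier vs non-carrier metagene at kept start-gain anchors
        if sg_kept:
            kept = sg.dedup_by_snv(sg_kept)
            anchors = [
                rp.Anchor(f"sg:{c.snv.variant_id}", human_by_id[c.transcript_id], c.novel_start_tpos)
                for c in kept
            ]
            carrier_sets = {f"sg:{c.snv.variant_id}": c.carrier_individuals for c in kept}

            def sg_group(sample_id: str, anchor_id: str) -> Optional[str]:
                return "carrier" if sample_id in carrier_sets[anchor_id] else "noncarrier"

            profiles, occ = rp.metagene(human_tracks, anchors, config.metagene_window, sg_group)
            prof_df = pd.concat([p.as_frame() for p in profiles.values()], ignore_index=True)
            _write(prof_df, "metagene_startgain.tsv")
            at0 = occ[occ.codon_offset == 0]
            cmp_sg = rp.compare_anchor_classes(
                at0[at0.group == "carrier"]["rpm"],
                at0[at0.group == "noncarrier"]["rpm"],
                paired=False,
            )
            summary["ribo"]["carrier_vs_noncarrier"] = cmp_sg

        # hSSC/hASC/cOSC/cSC metagene for analyzable human-specific codons
        if len(panel):
            usable = panel[panel.analyzable & ~panel.anchors_missing]
            for subset, tag in ((usable, "all"), (usable[~usable.cug_origin.astype(bool)], "non_cug")):
                h_anchors, c_anchors = [], []
                for _, r in subset.iterrows():
                    ht = human_by_id[r.transcript_id]
                    ct = chimp_by_id[r.chimp_transcript_id]
                    h_anchors.append(rp.Anchor(f"hssc:{r.transcript_id}", ht, int(r.hssc_tpos)))
                    h_anchors.append(rp.Anchor(f"hasc:{r.transcript_id}", ht, int(r.hasc_tpos)))
                    c_anchors.append(rp.Anchor(f"cosc:{r.transcript_id}", ct, int(r.cosc_tpos)))
                    c_anchors.append(rp.Anchor(f"csc:{r.transcript_id}", ct, int(r.csc_tpos)))
                cls_group = lambda sid, aid: aid.split(":")[0]
                h_prof, h_occ = rp.metagene(human_tracks, h_anchors, config.metagene_window, cls_group)
                c_prof, c_occ = rp.metagene(chimp_tracks, c_anchors, config.metagene_window, cls_group)
                if tag == "all":
                    prof_df = pd.concat(
                        [p.as_frame() for p in list(h_prof.values()) + list(c_prof.values())],
                        ignore_index=True,
                    )
                    _write(prof_df, "metagene_hss.tsv")

                def _paired(occ_df: pd.DataFrame, cls_a: str, cls_b: str) -> dict:
                    at0 = occ_df[occ_df.codon_offset == 0].copy()
                    at0["call"] = at0.anchor_id.str.split(":").str[1]
                    piv = at0.pivot_table(
                        index=["sample_id", "call"], columns="group", values="rpm"
                    ).dropna()
                    return rp.compare_anchor_classes(piv[cls_a], piv[cls_b], paired=True)

                summary["ribo"][f"hssc_vs_hasc_{tag}"] = _paired(h_occ, "hssc", "hasc")
                summary["ribo"][f"cosc_vs_csc_{tag}"] = _paired(c_occ, "cosc", "csc")

    if config.run_kaks and hss_calls:
        alignments = []
        for c in hss_calls:
            if c.novel_cds_len_nt < 3:
                continue
            try:
                alignments.append(
                    ce.extract_novel_cds_alignment(
                        c,
                        {t.transcript_id: t for t in human_transcripts},
                        {"chimpanzee": lifts["chimpanzee"], "gorilla": lifts["gorilla"]},
                        human_genome,
                    )
                )
            except ValueError as exc:
                log.info("alignment skipped: %s", exc)
        concat = ce.concatenate(alignments, config.concat_min_len_nt)
        fits = {}
        fits["single_omega"] = ce.fit_model(concat, foreground=None, seed=config.seed)
        lrts = {}
        for fg in ("human", "chimpanzee", "gorilla"):
            fits[f"foreground_{fg}"] = ce.fit_model(concat, foreground=fg, seed=config.seed)
            lrts[fg] = ce.lrt(fits["single_omega"], fits[f"foreground_{fg}"])
        kaks = {
            "n_cds_alignments": len(alignments),
            "n_cds_concatenated": len(concat.source_cds_ids),
            "n_codons": concat.n_codons,
            "fits": {
                name: {
                    "log_likelihood": f.log_likelihood,
                    "kappa": f.kappa,
                    "omega0": f.omega0,
                    "omega1": f.omega1,
                    "branch_lengths": f.branch_lengths,
                }
                for name, f in fits.items()
            },
            "lrt": {
                fg: {"statistic": r.statistic, "df": r.df, "p_value": r.p_value}
                for fg, r in lrts.items()
            },
        }
        path = os.path.join(config.out_dir, "kaks.json")
        with open(path, "w") as fh:
            json.dump(kaks, fh, indent=1, sort_keys=True)
        outputs.append(path)
        summary["kaks"] = {
            "omega_single": fits["single_omega"].omega0,
            "omega0_background": fits["foreground_human"].omega0,
            "omega1_human": fits["foreground_human"].omega1,
            "omega1_chimpanzee": fits["foreground_chimpanzee"].omega1,
            "omega1_gorilla": fits["foreground_gorilla"].omega1,
            "lrt_p_human": lrts["human"].p_value,
            "lrt_p_chimpanzee": lrts["chimpanzee"].p_value,
            "lrt_p_gorilla": lrts["gorilla"].p_value,
            "n_codons": concat.n_codons,
            "n_cds_concatenated": len(concat.source_cds_ids),
        }

    summary_path = os.path.join(config.out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    outputs.append(summary_path)

    manifest = {
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if not isinstance(v, (list,)) or k.endswith("samples")
        },
        "seed": config.seed,
        "outputs": {os.path.basename(p): _hash_file(p) for p in sorted(outputs)},
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest["outputs"], sort_keys=True).encode()
    ).hexdigest()
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    summary["manifest_hash"] = manifest["manifest_hash"]
    return summary
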