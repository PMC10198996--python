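"""Quantify ribosome occupancy at novel vs ancestral start codons.

Runs the footprint pipeline on simulated SAM files: length/uniqueness/
blacklist filtering, P-site inference (offset 11 for 26-29 nt reads, 12
for 30-32 nt), per-sample RPM tracks, and a carrier vs non-carrier
metagene around planted start-gain SNVs.
"""

import tempfile

from novostart import io as nio
from novostart import riboprofile as rp
from novostart import startgain as sg
from novostart.synthetic_data import FixtureConfig, make_fixture

with tempfile.TemporaryDirectory() as tmp:
    paths, truth = make_fixture(FixtureConfig(seed=0), tmp)
    genome = nio.read_genome(paths["fasta_human"])
    transcripts = {t.transcript_id: t for t in nio.read_gff3(paths["gff_human"])}
    snvs = nio.read_vcf(paths["vcf"])
    calls = sg.filter_for_occupancy(
        sg.dedup_by_snv(sg.call_all(snvs, list(transcripts.values()), genome))
    )
    blacklist = nio.read_bed_intervals(paths["blacklist"])

    tracks = []
    for sid in truth["ribo_samples"]:
        reads = nio.read_sam(paths[f"sam_{sid}"], sid, blacklist)
        tracks.append(rp.build_rpm_track(rp.filter_reads(reads), sid))

    anchors = [
        rp.Anchor(c.snv.variant_id, transcripts[c.transcript_id], c.novel_start_tpos)
        for c in calls
    ]
    carriers = {c.snv.variant_id: c.carrier_individuals for c in calls}
    grouping = lambda sid, aid: "carrier" if sid in carriers[aid] else "noncarrier"
    profiles, occ = rp.metagene(tracks, anchors, window_codons=5, grouping=grouping)

    print("codon offset vs mean RPM (0 = the novel start codon):")
    prof_c, prof_n = profiles["carrier"], profiles["noncarrier"]
    for k, vc in zip(prof_c.offsets, prof_c.mean_rpm):
        vn = prof_n.mean_rpm[prof_n.offsets.index(k)]
        print(f"  {k:+3d}  carrier {vc:9.1f}   non-carrier {vn:9.1f}")
    at0 = occ[occ.codon_offset == 0]
    res = rp.compare_anchor_classes(
        at0[at0.group == "carrier"]["rpm"], at0[at0.group == "noncarrier"]["rpm"], paired=False
    )
    print(
        f"\nanchor-codon occupancy: {res['fold_ratio']:.2f}x higher in carriers "
        f"(rank-sum p = {res['p_value']:.2g}; simulation planted "
        f"{truth['ribo']['carrier_fold']}x)"
    )
    # Carriers of the start-gain allele pile ribosome P-sites onto the novel
    # AUG; individuals without the allele show only flat background there.
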