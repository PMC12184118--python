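#!/usr/bin/env python
"""Leader annotation of the published 42-mer and a desk-scale co-occurrence
screen.

First annotates the LC-MS/MS-identified 42-residue N-terminal peptide of
MAM with the leader signature motif MMMPANx(8,11)VxGG (GG site, leader/
cargo split, positional consensus). Then emulates the genome screen on
synthetic data: 50 genomes, most carrying both a leader-motif protein and
a PCAT-motif protein, with Faecalibacterium-weighted taxon labels, and
verifies the screen recovers exactly the planted truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mampipe.io_formats import ProteinRecord
from mampipe.leader import annotate_leader, split_leader_cargo
from mampipe.motifs import parse_pattern
from mampipe.reference import LEADER_MOTIF_TEXT, MAM_NTERM_42, PCAT_MOTIF_TEXT
from mampipe.screen import cooccurrence_screen
from mampipe.simulate import simulate_genomes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--genomes", type=int, default=50)
    parser.add_argument("--out", type=Path, default=Path("results/motifs"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    mam42 = ProteinRecord(id="MAM_nterm42", sequence=MAM_NTERM_42)
    ann = annotate_leader(mam42)
    leader, cargo = split_leader_cargo(mam42, ann)
    leader_report = {
        "motif": LEADER_MOTIF_TEXT,
        "gg_start": ann.gg_start,
        "leader_length": ann.leader_length,
        "leader": leader,
        "cargo_prefix": cargo,
        "consensus_checks": {str(k): v for k, v in ann.consensus_checks.items()},
        "consensus_score": ann.consensus_score,
    }
    (args.out / "leader_annotation.json").write_text(
        json.dumps(leader_report, indent=2))
    print(f"42-mer leader: GG at {ann.gg_start}-{ann.gg_start + 1}, "
          f"leader {ann.leader_length} aa, consensus {ann.consensus_score}/6")

    proteins, truth = simulate_genomes(
        args.genomes, p_both=0.9, seed=args.seed,
        taxon_labels=("Faecalibacterium", "other"), taxon_weights=(0.95, 0.05),
        background_alphabet="ACDEFHKLNQRSTWY")  # G-free: no accidental hits
    report = cooccurrence_screen(proteins, parse_pattern(LEADER_MOTIF_TEXT),
                                 parse_pattern(PCAT_MOTIF_TEXT))
    pd.DataFrame([{"genome_id": g.genome_id, "has_mam": g.has_mam_motif,
                   "has_pcat": g.has_pcat_motif, "has_both": g.has_both}
                  for g in report.genomes]).to_csv(
        args.out / "genome_flags.tsv", sep="\t", index=False)
    screen_summary = {
        "n_genomes": report.n_genomes,
        "n_mam_proteins": report.n_mam_proteins,
        "n_genomes_with_both": report.n_genomes_with_both,
        "n_planted": len(truth.planted),
        "taxon_fraction": report.taxon_fraction,
        "recovered_equals_planted":
            report.n_genomes_with_both == len(truth.planted),
    }
    (args.out / "screen_summary.json").write_text(
        json.dumps(screen_summary, indent=2))
    frac = report.taxon_fraction.get("Faecalibacterium", 0.0)
    print(f"screen: {report.n_mam_proteins} leader-motif proteins across "
          f"{report.n_genomes} genomes; {report.n_genomes_with_both} genomes "
          f"carry both motifs (planted: {len(truth.planted)})")
    print(f"Faecalibacterium share of motif-positive proteins: {frac:.2%}")
    print(f"wrote tables under {args.out}/")


if __name__ == "__main__":
    main()
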