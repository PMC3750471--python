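#!/usr/bin/env python
"""OPTIONAL, NETWORK-REQUIRED: run the pipeline on the real ACTA1 panel.

Fetches the ten ACTA1 gene regions of the reference panel
(:data:`phasewarp.sequence_io.ACTA1_PANEL`) from NCBI via Entrez, then runs
the full pipeline: cumulated phase -> preprocessing -> pairwise DTW ->
normalized distance matrix -> UPGMA dendrogram with OTU-jackknife supports.

This script is NOT part of the test suite: it needs internet access and an
Entrez e-mail address.  Everything it does on real data is exercised
offline by the synthetic-family tests.

Usage:
    python scripts/acta1_study.py --email you@example.org --out-dir scratch/acta1
"""

from __future__ import annotations

import argparse
import time
from pathlib import Path

from Bio import Entrez, SeqIO

import phasewarp as pw
from phasewarp.cluster import jackknife_matrix
from phasewarp.sequence_io import ACTA1_PANEL


def fetch_panel(email: str, out_fasta: Path) -> list:
    Entrez.email = email
    records = []
    for entry in ACTA1_PANEL:
        region = entry.region
        print(f"fetching {entry.organism}: {region.accession} "
              f"{region.start}..{region.end}")
        handle = Entrez.efetch(
            db="nuccore",
            id=region.accession,
            rettype="fasta",
            retmode="text",
            seq_start=region.start,
            seq_stop=region.end,
        )
        rec = SeqIO.read(handle, "fasta")
        handle.close()
        label = entry.organism.replace(" ", "_")
        records.append(pw.DNASequence(id=label, seq=str(rec.seq).upper()))
        time.sleep(0.4)  # NCBI rate courtesy
    pw.write_fasta(records, out_fasta)
    return records


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="Entrez contact e-mail")
    parser.add_argument("--out-dir", type=Path, default=Path("scratch/acta1"))
    parser.add_argument("--jackknife", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    fasta = args.out_dir / "acta1_panel.fasta"
    if fasta.exists():
        print(f"reusing {fasta}")
        records = pw.read_fasta(fasta)
    else:
        records = fetch_panel(args.email, fasta)

    signals = [pw.preprocess(pw.cumulated_phase(r)) for r in records]
    matrix = pw.normalize_matrix(pw.pairwise_matrix(signals))
    matrix.write_tsv(args.out_dir / "distances.tsv")
    report = jackknife_matrix(matrix, replicates=args.jackknife, seed=args.seed)
    report.write_tsv(args.out_dir / "jackknife.tsv")
    tree = report.tree
    newick = tree.to_newick(include_support=True)
    (args.out_dir / "acta1_tree.nwk").write_text(newick + "\n")
    print(newick)


if __name__ == "__main__":
    main()
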