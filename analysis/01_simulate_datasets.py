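"""Generate the synthetic study datasets and write them to disk.

Produces, under scratch/sim/: a 1-Mb GC-0.6 genome with and without a
planted 10-bp AA/TT/TA comb (FASTA), an 85%-coding annotation (TSV), and
paired IP/input bedGraph tracks plus ground-truth JSON for the TF, NAP and
histone archetypes. Everything is seeded, so downstream scripts regenerate
the same data in memory instead of re-reading these files.
"""

from pathlib import Path

import bindmodes as bm
from bindmodes.io_formats import write_annotation, write_coverage, write_fasta
from bindmodes.synthetic import truth_coverage_fraction

GENOME_SEED, ANNOT_SEED, COV_SEED = 101, 102, 103
PLANT_SEED = 104
LENGTH, GC, N_GENES, CODING = 1_000_000, 0.6, 900, 0.85

out = Path(__file__).resolve().parent.parent / "scratch" / "sim"
out.mkdir(parents=True, exist_ok=True)

genome = bm.make_genome(LENGTH, GC, seed=GENOME_SEED)
write_fasta(genome, out / "genome.fasta")

planted = bm.plant_periodic_dinucleotides(genome, period=10, strength=0.3, seed=PLANT_SEED)
write_fasta(planted, out / "genome_planted10bp.fasta")

annotation = bm.make_annotation(genome, N_GENES, CODING, seed=ANNOT_SEED)
write_annotation(annotation, out / "genes.tsv")
cf = bm.coding_fraction(annotation, genome)
print(f"genome: {LENGTH:,} bp at GC {GC}; annotation: {N_GENES} genes, "
      f"coding fraction {cf:.3f}")

for mode in ("TF", "NAP", "histone"):
    ip, inp, truth = bm.simulate_chip_coverage(genome, annotation, mode, seed=COV_SEED)
    write_coverage(ip, out / f"{mode.lower()}_ip.bedgraph")
    write_coverage(inp, out / f"{mode.lower()}_input.bedgraph")
    truth.to_json(out / f"{mode.lower()}_truth.json")
    print(f"{mode}: {len(truth.planted_peaks)} planted intervals, "
          f"truth coverage {100 * truth_coverage_fraction(truth, genome):.2f}%")

print(f"wrote datasets to {out}")
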