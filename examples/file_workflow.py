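"""The file-based workflow: FASTA/GFF3/FASTQ/SAM in, TSV out.

Writes a small simulated library to disk, aligns the reads with the
built-in exact-match split aligner, and runs the end-to-end caller on the
SAM files exactly as the `ligr` command-line tool would. Also extracts
hybridization-predictor input windows (gene span +/- 50 nt when no UTR is
annotated) as FASTA.
"""

import tempfile
from pathlib import Path

from ligrseq import (SimConfig, call_interactions_end_to_end,
                     extract_significant, generate_genome, plant_pairs,
                     prediction_window, simulate_ligation, toy_align,
                     write_sam, write_windows)

workdir = Path(tempfile.mkdtemp(prefix="ligrseq_demo_"))
config = plant_pairs(
    SimConfig(genome_length=60_000, n_genes=30, n_srnas=6, n_reads=6_000,
              frac_chimeric=0.8, replicate_count=2, seed=19, circular=False),
    n_pairs=2, enrichment_fold=20.0)

genome, features = generate_genome(config)
genome.write_fasta(workdir / "genome.fa")
features.to_gff3(workdir / "annotation.gff3")

reads, truth = simulate_ligation(config, genome, features)
sam_paths = []
for rep, records in reads.items():
    alignments = toy_align(records, genome)
    path = workdir / f"rep{rep}.sam"
    write_sam(alignments, genome.chrom_lengths, path)
    sam_paths.append(path)
print(f"wrote genome, annotation and {len(sam_paths)} aligned replicates "
      f"to {workdir}")

results, info = call_interactions_end_to_end(
    sam_paths, workdir / "annotation.gff3")
print(f"N={info['N']} interaction reads, {info['n_pairs_tested']} pairs tested")
_, sig = extract_significant(results)
planted = {tuple(sorted(p[:2])) for p in config.planted_pairs}
print(f"FDR<0.05 pairs: {sig}")
print(f"planted pairs {sorted(planted)} recovered: {planted <= set(sig)}")

windows = [prediction_window(fid, features, genome)
           for a, b, _ in config.planted_pairs for fid in (a, b)]
write_windows(windows, workdir / "windows.fa")
print(f"hybridization-prediction windows for the significant partners "
      f"written to {workdir / 'windows.fa'}")
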