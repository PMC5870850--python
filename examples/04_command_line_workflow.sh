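#!/usr/bin/env bash
# End-to-end shell workflow: simulate a fixture cohort, pre-compute the
# ancestry space, then place study samples from a VCF (genotype mode) and
# from read counts (sequence mode). Outputs are tab-separated placement
# tables plus a JSON manifest per run.
set -euo pipefail
workdir="$(mktemp -d)"

pcaplace simulate --pops 3 --n-per-pop 50 --sites 2000 --fst 0.1 \
    --depth 5 --error 0.01 --seed 42 --n-study-per-pop 5 --out-dir "$workdir"

pcaplace build-space --panel-prefix "$workdir/panel" --out-prefix "$workdir/world" --K 4

pcaplace place-genotypes --panel-prefix "$workdir/panel" \
    --space-prefix "$workdir/world" \
    --vcf "$workdir/study.vcf" --out "$workdir/genotype.placements.tsv"

pcaplace place-reads --panel-prefix "$workdir/panel" \
    --space-prefix "$workdir/world" \
    --pileup "$workdir/study.pileup" --siterr "$workdir/study.siterr" \
    --seed 7 --out "$workdir/sequence.placements.tsv"

echo "--- genotype-mode placements (sample_id, L_used, t, Z, PC1..PC4, kNN) ---"
head -6 "$workdir/genotype.placements.tsv" | cut -f1-8 | expand -t14
echo "results in $workdir"
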