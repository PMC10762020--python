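#!/bin/sh
# Full shell workflow: synthesize a record, estimate RR from the binary
# file, then score the estimate against the generator's ground truth.
set -e

OUT=${1:-/tmp/ecgresp_demo}

ecgresp synth --hr 60 --rr-sine 12,5,300 --duration 600 --fs 500 \
    --seed 3 --out-dir "$OUT/synth"

ecgresp estimate --input "$OUT/synth/ecg.bin" --format bin16 \
    --fs 500 --scale 0.001 --resample-fs 0 --median-window 8 \
    --out-dir "$OUT/estimate"

ecgresp eval --est "$OUT/estimate/rr.csv" --ref "$OUT/synth/truth.csv" \
    --out-dir "$OUT/eval"
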