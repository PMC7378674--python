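#!/bin/sh
# Full pipeline from the shell: simulate -> preprocess -> extract ->
# train -> evaluate, in a scratch directory.
set -e
work=$(mktemp -d)

zonelvq simulate --n-normal 10 --n-suspected 10 --seed 1 --out "$work/train"
zonelvq simulate --n-normal 10 --n-suspected 10 --seed 2 --prefix test --out "$work/test"

zonelvq preprocess "$work"/train/phantom-*.png --out "$work/bin"

zonelvq extract "$work"/train/phantom-*.png \
    --labels "$work/train/labels.csv" --out "$work/train_features.csv"

zonelvq train --features "$work/train_features.csv" --out "$work/model.json"

zonelvq evaluate "$work"/test/test-*.png \
    --model "$work/model.json" --labels "$work/test/labels.csv" \
    --out-csv "$work/results.csv" --out-json "$work/metrics.json"

cat "$work/metrics.json"
rm -rf "$work"
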