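#!/usr/bin/env bash
# End-to-end command-line workflow: generate a dataset, train the tiny
# preset on it, evaluate the checkpoint, and inspect parameter counts.
#
# Run from the repository root:  bash examples/04_cli_workflow.sh
set -euo pipefail

DATA=scratch/cli_dataset
RUN=scratch/cli_run

hfseg generate --n 8 --size 64 --seed 0 --out "$DATA"

# A short demonstration run; drop --epochs for the full 50-epoch schedule.
hfseg train --data "$DATA" --preset tiny --epochs 10 --batch-size 8 \
    --seed 0 --out "$RUN"

hfseg eval --data "$DATA" --checkpoint "$RUN/checkpoint.npz"

hfseg params --preset tiny
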