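# barcodeaudit

Audited analysis of DNA-barcode reference libraries: Kimura-2-parameter
pairwise distances with pairwise deletion, neighbor-joining trees with
nonparametric bootstrap support and midpoint rooting, per-species
monophyly and diagnosability classification (barcode-cluster and
species-specific-haplotype criteria), shared-haplotype detection,
cryptic-diversity screens, singleton query identification, integrative
(morphology + barcode) identification-rate tables, and a synthetic
library simulator with known ground truth for end-to-end validation.

## Test

```bash
python -m pytest -q tests/
```

The suite includes independent brute-force oracles (per-character K2P
site counting, random additive trees for NJ consistency, exhaustive
nearest-neighbor loops) in `tests/oracles.py`, property tests
(hypothesis), and `tests/test_acceptance.py` with one test per
acceptance criterion.

## CLI

```bash
# full audit: FASTA + metadata TSV -> matrix, NJ tree, per-species table,
# summary JSON (optionally an integrative rate table)
barcodeaudit audit library.fasta metadata.tsv -o out/ \
    --replicates 100 --seed 1 [--morphology morph.tsv]

# synthetic library with ground truth from a YAML config
barcodeaudit simulate sim.yaml -o simdir/

# integrative identification-rate table (packaged fixture by default)
barcodeaudit table1 -o rates.json

# coverage of a reference species list
barcodeaudit coverage reference_species.txt library.fasta metadata.tsv
```

Input conventions: FASTA sequences must be pre-aligned (equal length;
lowercase and U are normalized, IUPAC ambiguity codes other than N map
to N with a warning). The metadata TSV is tab-separated with a header
and requires `specimen_id` and `species` columns (`sex`, `region`
optional). Morphology-difficulty annotations are a TSV with
semicolon-separated `members`, `sex` (male/female), `difficult` and an
optional `note`; an editable fixture for the Swiss diurnal Lepidoptera
library ships in `src/barcodeaudit/data/`.

## Library API

```python
from barcodeaudit import (
    read_fasta, distance_matrix, nj_build, bootstrap_support,
    midpoint_root, audit_library, identify_query,
    SimulationConfig, simulate_library,
)

lib = read_fasta("library.fasta", "metadata.tsv")
report = audit_library(lib, bootstrap_replicates=100, seed=1)
print(report.summary()["monophyly_counts"])
```

## Conventions worth knowing

- Distances are stored in substitutions/site and reported in percent;
  percentages are rounded half-up to 1 decimal only at serialization.
- Saturated pairs (log argument <= 0) get an *undefined* distance, never
  a clamp; they are tracked per pair and poison downstream steps loudly.
- A shared barcode is a K2P distance of exactly zero under pairwise
  deletion (not string equality).
- NJ tie-breaking, bootstrap resampling and the simulator are
  deterministic given a single integer seed.
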