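# pocketassess

Functional-relevance assessment of predicted protein structures.

Instead of asking only "how close is the model to the experimental
structure?", this package asks "does the model reproduce the
physicochemical microenvironments of the functional site?". It:

- featurizes spherical **microenvironments** (7.5 Å radius, six 1.25 Å
  shells × 80 physicochemical property rules = a 480-dimensional
  descriptor) around functional-site centers;
- scores site similarity between a reference structure and predicted
  models with a standardized **Tanimoto** similarity and a mutual-best-match
  alignment of center pairs (more negative total = more similar than the
  random background);
- computes companion structural metrics (**Kabsch RMSD, GDT_TS, TM-score,
  site-local RMSD**) and ranks model ensembles functionally vs structurally,
  with z-scoring in *all-models* and *model-1* modes, RMSD filtering, top-k
  selection, Spearman rank correlation, and solvent-exposure accuracy
  metrics for variant sites;
- ships a **synthetic-data generator** (concave-pocket reference structures,
  optionally ligand-bound, plus noise-graded model ensembles with separable
  global/site-local noise and optional "good site / bad fold" injections)
  and a packaged transcription of the 28-site functional-site inventory
  (9 holo / 9 apo / 10 critical patches).

## Quick start (Python)

```python
from pocketassess import (EnsembleConfig, Featurizer, generate_ensemble)
from pocketassess.assessment import (background_from_structures, rank_by,
                                     score_ensemble, spearman, zscore_records)
from pocketassess.synthetic_data import perturb_model

ens = generate_ensemble(EnsembleConfig(n_residues=60, n_models=50, seed=0))
fz = Featurizer()
decoys = [perturb_model(ens.reference, s, 0.0, None, seed=i)
          for i, s in enumerate([0.3, 0.6, 1.0, 1.5])]
bg = background_from_structures([ens.reference] + decoys, fz, seed=0)

records, excluded = score_ensemble(ens.reference, ens.site, ens.models, bg,
                                   featurizer=fz)
records = zscore_records(records, mode="all_models")
records = rank_by(records, "pf_zscore")
records = rank_by(records, "gdt_ts")
rho = spearman([r.rank_functional for r in records],
               [r.rank_structural for r in records])
```

## CLI

```bash
pocketassess synth --n-residues 60 --n-models 50 --seed 0 --out scratch/ens
pocketassess build-background scratch/ens/reference.pdb scratch/ens/S0*_*.pdb \
    --seed 0 --out scratch/background.json
pocketassess compare-sites scratch/ens/reference.pdb scratch/ens/S01_1.pdb \
    scratch/ens/site.yaml --background scratch/background.json --out scratch/aln.tsv
pocketassess assess scratch/ens --background scratch/background.json \
    --out scratch/assessment.tsv
pocketassess report scratch/assessment.tsv --top-k 30 --out-prefix scratch/rep
pocketassess featurize scratch/ens/reference.pdb scratch/ens/site.yaml \
    --out scratch/features.tsv
```

Structures are read/written as PDB; predicted models may use the CASP-TS
dialect (`PFRMAT TS` / `TARGET` / `MODEL` headers). Site definitions are
small YAML files (target, category holo/apo/patch, residue selectors like
`A:145`, optional ligand code).

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: descriptor and
fixture contracts, invariance suites (rigid-motion invariance of the
descriptor and of GDT/TM/RMSD, shell conservation, Tanimoto bounds,
z-score normalization), oracle-equivalence checks (alignment vs an
exhaustive greedy oracle, GDT vs an exhaustive-superposition oracle,
Spearman vs the rank formula), and seeded parameter-recovery runs on
synthetic ensembles. The parameter-recovery test takes a few minutes.

## Notes on scope

- Official CASP rankings and predictions are not fetched; the structural
  metrics here are stand-ins used for synthetic experiments and are not
  bit-for-bit reproductions of LGA/TM-score binaries (small cases are
  verified against exhaustive oracles instead).
- De novo pocket detection, conservation scoring, and solvent-accessibility
  computation are out of scope; accessibility values are consumed as inputs.
- The 80-rule property manifest (`src/pocketassess/data/property_manifest.yaml`)
  is data, not code: any 80-rule manifest of orientation-independent,
  per-atom rules is admissible.
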