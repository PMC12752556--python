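# cytofna

Desk-scale thyroid fine-needle-aspiration (FNA) cytology diagnosis pipeline.

Thyroid nodules are triaged by FNA cytology under the Bethesda system
(TBSRTC): category I (nondiagnostic), II (benign), V (suspicious for
malignancy), VI (malignant). `cytofna` implements the full computational
path from raw smear tiles to a slide-level Bethesda call:

* a **synthetic smear generator** that renders Papanicolaou/H&E-styled
  patches with exact instance masks, 17-category cell labels, a
  deterministic slide-level TBS label and a BRAF-V600E status — every model
  below is trained and validated offline against it;
* **nuclear segmentation** with a compact pyramid-fusion U-Net (pure-numpy
  training, ~30 k parameters — under 1% of a VGG16-backbone
  DeepLab-v1-style reference), HSV colour filtering of red-blood-cell
  debris, and watershed post-processing into scored nucleus/cluster
  detections;
* **19-feature nuclear morphometry** and a gradient-boosted morphology
  classifier;
* a **large-kernel-attention cell classifier** (17-way) with a dual-model
  *agreement gate*: papillary (C1–C3) and benign-follicular (C6–C8) calls
  survive only when the network and the morphology model agree;
* **104-attribute slide features** (per-role counts, probability /
  detection-score / area statistics, nuclear-morphometry aggregates);
* **two-step diagnosis**: the adequacy rule
  `10·(N-PTCA + N-TFECA) + 5·(N-PTCB + N-TFECB) < 60  →  TBS I`,
  then a grid-searched, 5-fold cross-validated XGBoost classifier
  (3-class II/V/VI or 2-class II vs V+VI); an optional **cascade** consults
  a BRAF classifier whenever the image model outputs TBS V and resolves it
  to II (wild-type) or VI (mutant);
* **image appearance migration (IAM)**: cytology-specific foreground
  masking plus slide-level CIELAB statistics matching to a reference
  domain, for cross-scanner/stain robustness.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import numpy as np
from cytofna.pipeline import (train_fixture_models, tile128_config,
                              cohort_features)
from cytofna.synthcyto import sample_cohort
from cytofna.diagnose import train_wsi_gbt, predict_tbs

models = train_fixture_models(seed=0)          # seg + cell + morphology GBT
cfg = tile128_config()
train = sample_cohort(150, seed=101)           # slides with known TBS labels
test = sample_cohort(200, seed=202)

xtr, ytr, _ = cohort_features(train, models, cfg)
adequate = [i for i, l in enumerate(ytr) if l != "I"]
wsi = train_wsi_gbt(xtr.iloc[adequate], [ytr[i] for i in adequate],
                    n_classes=3, seed=0)
print(f"cv accuracy: {wsi.cv_accuracy:.3f}")

xte, yte, _ = cohort_features(test, models, cfg)
finals = [predict_tbs(xte.iloc[i], wsi).final for i in range(len(xte))]
print(f"end-to-end accuracy: {np.mean([f == t for f, t in zip(finals, yte)]):.3f}")
```

Output from this exact run:

```
cv accuracy: 0.852
end-to-end accuracy: 0.865
```

The cross-validated accuracy (0.852) is the 3-class image classifier on the
adequate training slides; the end-to-end number (0.865) is the fraction of
200 held-out slides whose final label (adequacy rule + classifier) matches
the generator's ground truth across all four categories I/II/V/VI.

A command-line interface mirrors the library (`cytofna synth|train-seg|
train-cell|train-morpho|detect|run|evaluate ...`); detections are exchanged
as GeoJSON/CSV, profiles and reports as JSON, datasets as PNG + CSV +
manifest JSON.

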