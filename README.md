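# lispcn

Joint synthesis of early-treatment breast DCE-MRI and prediction of
response to neoadjuvant chemotherapy (NAC), in one multitask network.

## The problem

During NAC, tumors change early: responders often show concentric
shrinkage within the first cycles.  Imaging at that early time point
improves prediction of pathological complete response (pCR), but the
clinically useful decision moment is *before* treatment starts, when
only the preoperative scan exists.  `lispcn` trains a model that, from a
preoperative dynamic contrast-enhanced MRI stack (series S0, S3, S5 as
three channels), simultaneously

* **synthesizes** the patient's early-treatment image, and
* **predicts** the binary pCR outcome,

with both tasks sharing one latent feature map `z`.  The synthesis task
forces `z` to encode treatment-relevant change, which is exactly the
information the classifier needs — the multitask coupling is the point.

## The model

A cycle-consistent adversarial pair: generator `G` (pre → early) and `F`
(early → pre), each an encoder (three stride-2 conv stages, widths
2/4/8, efficient channel attention after each stage) and a mirror
decoder with skip connections and a global residual path.  Patch-GAN
critics `D1`, `D2` score each domain.  A small MLP head on globally
pooled `z` outputs `P(pCR)`.  The generator objective is

```
adv(G) + adv(F) + λ_cyc‖F(G(x)) − x‖₁-type cycle
              + λ_cls · weighted BCE + λ_pcp · paired perceptual
```

with least-squares adversarial terms and Adam(0.5, 0.99), batch 8,
learning rates 2·10⁻³ (GAN) / 10⁻⁴ (head), ×0.97 every 50 epochs.
Everything runs on a built-in numpy autodiff core — no GPU or deep
learning framework required.

Because no patient data ships with the package, a phantom module
generates paired longitudinal cohorts with known ground truth:
elliptical enhancing lesions on textured parenchyma, contrast ordering
S0 < S3, tumor shrinkage between time points, and a pCR label drawn from
a logistic link on shrinkage.  Enhancement and washout kinetics carry
the response signal into the pre-treatment image, so recovery of the
label from pre-NAC input is a well-posed test.  See `docs/methods.md`.

## Worked example

```python
import numpy as np
from lispcn import LISPCNModel, generate_cohort
from lispcn.evalmetrics import ssim

train_cases = generate_cohort(n=50, prevalence_target=0.2, size=64, seed=7)
test_cases  = generate_cohort(n=30, prevalence_target=0.2, size=64, seed=99)

model = LISPCNModel(max_iterations=300, seed=0).fit(train_cases)

auc = model.score(test_cases)                  # held-out AUC
synth = model.transform(test_cases[:1])[0]     # synthetic early-NAC stack
s_synth = ssim(synth, test_cases[0].early_image)
s_copy  = ssim(test_cases[0].pre_image, test_cases[0].early_image)
print(f"held-out AUC {auc:.3f}")
print(f"SSIM synthetic {s_synth:.3f} vs copy-input baseline {s_copy:.3f}")
```

Output with exactly these seeds:

```
held-out AUC 0.963
SSIM synthetic 0.644 vs copy-input baseline 0.642
```

The AUC says the classifier recovers the planted response signal from
pre-treatment images alone (slice-level, on a small 30-patient cohort —
expect noticeable seed-to-seed spread); the SSIM pair says the
synthesized early image is closer to the true early image than simply
presenting the unchanged pre-treatment scan.

The same pipeline is scriptable from the shell:

```bash
lispcn simulate --n 50 --seed 7 --out data/
lispcn train    --manifest data/manifest.csv --iterations 300 --out run/
lispcn evaluate --checkpoint run/checkpoint.pkl --manifest data/manifest.csv --out eval/
lispcn explain  --checkpoint run/checkpoint.pkl --manifest data/manifest.csv --out cam/
```

Ablation variants (`AS-Dec`, `AS-Dis`, `AS-GF`, `AS-Pcp`) drop one
component each (`lispcn ablate --variant AS-Dec …`); head-only
fine-tuning for cohort transfer is `lispcn finetune`.

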