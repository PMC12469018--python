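# neurolatent

Interpretable self-supervised modeling of multi-component neural time series.
The package is aimed at computational-psychiatry researchers working with
subject-level ICA time courses from resting-state fMRI (T time points × 53
components per subject) who want both a case/control classifier and a
network-level account of what it learned.

## What it does

1. **Time-reversal (TR) pretraining.** An unlabeled corpus is doubled with
   time-reversed copies X̃ = {x_T, …, x_1} and a hierarchical recurrent model
   f_θ is trained to classify direction, minimizing

   L = −E[ y·log f_θ(X̃) + (1−y)·log f_θ(X) ],

   which forces the encoder to learn the temporal asymmetry of hemodynamic
   dynamics without any labels.
2. **Hierarchical dual-attention architecture.** The series is windowed
   (20 time points per window), each window runs through an LSTM encoder
   (53 → 256), window-level additive attention pools time steps, a main LSTM
   (hidden 200) with global attention pools windows into a subject latent
   z ∈ R²⁰⁰, and a linear decoder emits 2 logits.
3. **Transfer + evaluation grid.** Pretrained weights (minus the decoder)
   initialize diagnostic fine-tuning; the protocol crosses 5 pretraining
   checkpoints × 5 stratified folds × 4 seeds = 100 cells, with a
   from-scratch (NPT) baseline arm. Performance is rank-based AUC.
4. **Mahalanobis balancing.** Imbalanced cohorts keep only the k controls
   nearest (in Mahalanobis distance of time-averaged component activity) to
   the patient distribution — e.g. 100 of 433 controls for a 433/66 cohort,
   261 of 651 for 651/172.
5. **Probing + attribution.** Latent features are validated with one- and
   two-sample t-tests (Benjamini–Hochberg FDR, q < 0.05), probed with
   cross-validated logistic regression, and the coefficients β are mapped
   back to components through the attention-scaled weight product

   M = Σ_k Σ_t (α_global[k]·W_main) @ (α_win[k,t]·W_enc)  ∈ R^(200×53),

   then averaged within seven functional networks (Subcortical, Auditory,
   Sensorimotor, Visual, Cognitive Control, Default Mode, Cerebellar).
   A network suppressed in patients receives a negative importance score.
   Cross-cohort agreement is the Pearson correlation of two cohorts'
   network-score vectors.

Real clinical datasets in this field are access-controlled, so the package
ships a synthetic-cohort generator that plants the statistical structure the
method relies on: temporally asymmetric dynamics (sparse events convolved
with a fast-rise/slow-decay kernel) so time direction is learnable, and
case/control cohorts whose designated networks carry amplitude or
temporal-dynamics differences, giving every experiment a known ground truth.
The model and optimizer run on a small in-repo reverse-mode autodiff engine
over NumPy (float64, gradient-checked), so there is no GPU dependency.

## Worked example

Run the end-to-end synthetic study (generate corpus + two cohorts with a
suppressed-Auditory signature, pretrain, fine-tune PTR and NPT arms, probe,
attribute, compare cohorts):

```bash
neurolatent run --seed 7 --out runs/demo
```

which printed, after about ten minutes on one CPU:

```json
{
  "seed": 7,
  "pretrain_tr_auc": [1.0, 1.0, 1.0, 1.0, 0.965],
  "finetune_auc": {"PTR": 0.740, "NPT": 0.829},
  "consistency": {"PTR": 0.950, "NPT": 0.961},
  "n_sig_two": {"PTR": 13.75, "NPT": 13.25}
}
```

Reading the numbers: every pretraining fold separates original from reversed
series essentially perfectly (TR-AUC ≈ 1.0) — the pretext signal is there.
Both arms classify patients well above chance; on this *amplitude* signature
the scratch arm actually edges out the pretrained one, because amplitude
information is invisible to the TR pretext (see the methods note for why,
and for the dynamics signatures where pretraining does help). The
attribution recovers the planted effect: `runs/demo/importance_PTR_COHORT-A.csv`

```
network,mean,sd,n_cells
Subcortical,0.0034,0.0374,2
Auditory,-0.2552,0.0685,2
Sensorimotor,-0.0129,0.0131,2
Visual,0.0204,0.0045,2
Cognitive Control,0.0222,0.0291,2
Default Mode,-0.0049,0.0420,2
Cerebellar,-0.0328,0.0044,2
```

The Auditory network — whose amplitude was halved in patients — is the most
negative score by an order of magnitude (negative = patient-associated under
the probe's sign convention), and both cohorts agree on the network ranking
(Pearson r ≈ 0.95).

Individual stages are available as `neurolatent
{simulate,pretrain,balance,finetune,stats,probe,map}`; library functions
mirror each subcommand.

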