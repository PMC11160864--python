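# hlfd — hierarchical layer-selective feedback distillation

Compact segmentation networks for CT tumor delineation (kidney, liver)
lose most of their accuracy exactly where it matters: small, low
contrast lesions. `hlfd` implements a knowledge-distillation framework
that recovers part of that gap by routing a large frozen teacher's
knowledge *backwards* through the student's layer hierarchy — middle
layers teach early layers, the final layer teaches the middle layers —
at both the feature and the pixel level. It is written for researchers
who want a fully inspectable, CPU-runnable reference of the method:
every component is a pure function over numpy-backed tensors, the
networks are miniature but faithful analogues, and a built-in CT
phantom generator makes the whole study reproducible without any
dataset download.

## The objective

With encoder taps `z_early, z_mid_j (j=1..N), z_late` for student `s`
and frozen teacher `t`, and `A(·)` the spatial attention operator
(resample, sum of absolute activations over channels, flatten,
L2-normalize), the student minimizes

    L = L_seg + β·(L_UFD + L_IFD) + λ·(L_UPD + L_IPD)        β=0.9, λ=0.1

    L_UFD = ‖ A(z_early^s) − A(z_mid^t) ‖₂          unified mid → early
    L_IFD = Σ_j ‖ A(z_mid_j^s) − A(z_late^t) ‖₂     late → each mid
    L_UPD = KL( p_early^s ∥ p_mid^t )               unified mid map → early map
    L_IPD = (1/N) Σ_j KL( p_mid_j^s ∥ p_late^t )    terminal map → each mid map

where `z_mid^t` concatenates the teacher's middle features at the
smallest middle resolution, `p_mid^t` averages the teacher decoder's
middle predictive maps, the student's `p` maps come from discardable
1×1 auxiliary heads, and `L_seg` is a focal-dice loss. At inference
the teacher and all auxiliary heads are discarded. See
`docs/methods.md` for the full specification of every term and every
numerical choice.

## Worked example

```python
from hlfd import TrainConfig, freeze, generate_phantoms
from hlfd import pipeline as pl

train = generate_phantoms(100, size=64, organ="kidney", difficulty="easy", seed=0)
val   = generate_phantoms(25,  size=64, organ="kidney", difficulty="easy", seed=1000)

teacher_run = pl.train_teacher(TrainConfig(epochs=14, seed=0), train, val_data=val)
print(f"teacher val DSC: {teacher_run.val_report.dsc_mean:.3f}")

student_run = pl.distill_student(TrainConfig(epochs=10, seed=0),
                                 freeze(teacher_run.network), train, val_data=val)
last = student_run.log[-1]
print("final-epoch loss breakdown:",
      {k: round(last[k], 3) for k in ("seg", "ufd", "ifd", "upd", "ipd", "total")})
print(f"distilled student val DSC: {student_run.val_report.dsc_mean:.3f} "
      f"(RVD {student_run.val_report.rvd_mean:+.3f})")
```

prints (about four minutes on one CPU):

```
teacher val DSC: 0.806
final-epoch loss breakdown: {'seg': 0.42, 'ufd': 0.081, 'ifd': 0.223, 'upd': 1.802, 'ipd': 0.508, 'total': 0.924}
distilled student val DSC: 0.736 (RVD -0.121)
```

The 75k-parameter teacher reaches DSC 0.806 on easy phantoms after 14
epochs; the 34k-parameter student, distilled for 10 epochs, reaches
0.736 — most of the teacher's accuracy at under half the size. The
breakdown shows all five loss components live at the end of training:
`seg` is the supervised focal-dice term, `ufd`/`ifd` the attention
terms (weighted by β=0.9 in `total`), `upd`/`ipd` the pixel-KL terms
(weighted by λ=0.1). The slightly negative RVD means the student
under-segments lesion volume by ~12% on average.

The same study is available from the shell:

```
hlfd gen-data      --config cfg.yaml --out data/
hlfd train-teacher --config cfg.yaml --data data/ --out runs/teacher
hlfd distill       --config cfg.yaml --data data/ --teacher runs/teacher/teacher --out runs/student
hlfd evaluate      --checkpoint runs/student/student --data data/ --out runs/metrics
```

with a YAML config holding `data / model / train / loss` sections
(`hlfd distill --no-kd` trains the supervised baseline instead).

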