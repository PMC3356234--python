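# chondrosim

Reaction–diffusion–delay simulation of cartilage lesion expansion and
abatement, for modellers studying post-traumatic osteoarthritis and
the cytokine "balancing act" that decides whether an injury stays
contained.

After a blunt injury to articular cartilage, necrotic cells release
alarmins (DAMPs) that switch nearby healthy chondrocytes into a
catabolic state; catabolic cells secrete TNF-α and reactive oxygen
species, TNF-α degrades matrix (releasing more DAMPs) and converts
more healthy cells — a self-amplifying loop that spreads a lesion far
beyond the original wound.  Healthy cells signalled by ROS respond,
after a ~24 h delay, by secreting erythropoietin (EPO); catabolic
cells express the EPO receptor after a ~12 h delay and can be rescued
back to health.  Whether the lesion expands without limit or is
abated at a fixed radius depends on the race between these two arms.

`chondrosim` implements this as nine coupled fields on a radially
symmetric disc — four diffusing chemicals R (ROS), M (DAMPs),
F (TNF-α), P (EPO); matrix density U; and immobile cell-state
densities C (healthy), S_T (catabolic), S_A (EPOR-active),
D_N (necrotic) — with Michaelis–Menten kinetics x/(λ+x), two discrete
delays τ₁, τ₂, and a hard threshold gate H(P − P_c) that permits the
healthy → catabolic switch only while EPO is below a critical level,
e.g.

    ∂t P = ∇·(D_P ∇P) − δ_P P + σ_P C · R(t−τ₂)/(λ_R + R(t−τ₂)) · Λ/(Λ+F)
    ∂t C = α S_A P/(λ_P+P) − [β₁ M/(λ_M+M) + β₂ F/(λ_F+F)] C H(P−P_c)

The method of lines (conservative finite volumes on annuli) reduces
the PDEs to a large delay-differential system, integrated by the
method of steps with an explicit embedded Runge–Kutta 2(3) pair and
cubic-Hermite dense output.  See `docs/methods.md` for the full model,
the numerical choices and the calibration rationale.

## Worked example

```python
import chondrosim as cs

traj = cs.run_with_epo()                   # shipped 10-day reference run
summary = cs.summarize(traj, 100.0)        # C0 = 100 cells/mm^2
print(cs.classify_regime(summary, 100.0, 0.25))
print(f"abatement day:       {cs.abatement_day(summary):.2f}")
print(f"penumbra radius d10: {summary.penumbra_outer_mm.iloc[-1]:.2f} mm")
print(f"healthy cells d10:   "
      f"{100 * summary.int_C.iloc[-1] / summary.int_C.iloc[0]:.1f} %")
```

prints

```
abated
abatement day:       3.88
penumbra radius d10: 3.34 mm
healthy cells d10:   88.4 %
```

meaning: the lesion stops expanding just before day 4, the ring of
sick (catabolic + EPOR-active) cells freezes at about 3.3 mm and no
longer grows between day 7 and day 10, and by day 10 the healthy
population has recovered to 88% of its pre-injury total.  Running the
same injury with EPO production switched off
(`cs.run_no_epo()`) instead classifies `expanding`, with the healthy
population decimated to 4.4% by day 10 — the two runs are
bit-identical for the first 24 h, because the EPO pathway cannot act
before its delays elapse.

The same experiments are available from the shell:

```bash
chondrosim simulate --scenario with_epo --out run.h5 --csv run.csv
chondrosim metrics run.h5 --out summary.csv
chondrosim sensitivity --params sigma_P,sigma_F --out sens/
chondrosim convergence
```

Every CLI run writes a JSON manifest (config hash, tolerances, step
counts) next to its outputs.

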