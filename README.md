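# alesense

Off-gas soft sensing and repeated-batch process simulation for adaptive
laboratory evolution (ALE) in stirred-tank bioreactors.

## The problem

ALE experiments that select for faster growth pass a bacterial culture
through dozens of sequential batches. In an automated repeated-batch
reactor, passaging is triggered by the dissolved-oxygen (DO) spike that
accompanies carbon-source depletion, and the only continuous readout of the
culture's state is the off-gas: the O₂ and CO₂ fractions leaving the vessel.
`alesense` turns those off-gas time series into the quantities an evolution
experiment is actually about — per-batch biomass trajectories, specific
growth rates μ, generations, cumulative cell divisions (CCD), and the point
at which the evolving population reaches a stable phenotype — and ships a
mechanistic simulator of the whole repeated-batch process so that every
stage of the analysis can be exercised and validated without an instrument.

It is written for bioprocess engineers and quantitative microbiologists who
run (or plan) automated serial-passaging experiments with *E. coli* on
glycerol or similar aerobic single-substrate systems.

## The model

Growth is summarised by a black-box macro-chemical equation on a C-mole
basis (every carbon compound normalised to one carbon atom):

```
rs·CH2.67O + ro·O2 + rn·NH3  →  rx·CH1.77O0.49N0.24 + rc·CO2 + rw·H2O
```

Two balances close the system: the carbon balance `rs = rx + CER` and the
degree-of-reduction (electron) balance `rs·γs = rx·γx + 4·OUR`, with
γ(glycerol) = 4.67 and γ(biomass) = 4.19 under the scheme γC=4, γH=1,
γO=−2, γN=−3. Eliminating rs gives the biomass and substrate rates as
linear combinations of the two measurable gas rates,

```
rx = 8.33·OUR − 9.73·CER          rs = 8.33·OUR − 8.73·CER
```

where OUR and CER (mol L⁻¹ h⁻¹) come from the inert-gas balance over the
vessel: `OUR = F/(Vm·Vr)·[y_O2,in − (I_in/I_out)·y_O2,out]` and analogously
for CO₂. Trapezoidal integration of rx, scaled by the C-mole mass of
biomass (24.996 g mol⁻¹), yields cx(t); μ is the log-linear slope of cx
over the trailing half of each batch; cell counts N = cx·Vr/m_cell
(m_cell = 2.90·10⁻¹³ g) give generations n = log₂(N/N₀) per batch and
CCD = Σ N₀,ᵢ·(2^nᵢ − 1) across batches. A population is *stable* once
three consecutive μ̂ values have SD < 0.01 h⁻¹ and no further upward trend;
relative fitness is the stable μ divided by a reference group's stable μ.

## Worked example

Simulate a 22-batch evolution run (growth rate adapting 0.30 → 0.61 h⁻¹,
realistic sensor noise) and analyze it end to end:

```
$ alesense simulate --config run.yaml --out data/
simulated 22 batches, 39891 samples -> data/series.csv
$ alesense analyze --in data/ --config run.yaml --out res/
analyzed 22 batches (22 kept); summary -> res/summary.json; stable mu = 0.595 /h
$ alesense report --in res/
repeated-batch ALE run summary
===============================
batch duration_h mu_hat_1/h
    1      12.10      0.362
    2       9.06      0.386
    ...
   21       5.63      0.600
   22       5.93      0.600

evaluated batches : 22
discarded batches : []
stable phenotype  : batch 16 (index 15)
stable mu         : 0.595 1/h
total CCD         : 2.872e+14 (log10 14.46)
```

Reading this: batch durations shrink from ~12 h to ~6 h as the culture
adapts (lag phases vanish and μ rises), every batch passes the R² ≥ 0.98
fit-quality gate, the stability criterion first holds at batch 16, and the
mean growth rate over the stable phase is 0.595 h⁻¹ — within 2.5% of the
generator's 0.61 h⁻¹ ceiling, the residual gap being the adaptation law's
asymptotic tail at the detection point. The run accumulated ~2.9·10¹⁴
cell divisions. The same pipeline is available as a library
(`alesense.analyze_series`) operating on any CSV with columns
`time_s, do_pct, ph, y_o2_pct, y_co2_pct, conductivity_ms[, phase]` on a
uniform 15-s grid.

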