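# isletchip

Glucose–insulin homeostasis modelling for a two-compartment liver–islet
microphysiological system ("organ-on-chip"), with experiment-wise
calibration and in-vitro → in-vivo translation.

The package is aimed at systems biologists and MPS experimentalists who
want to (i) interpret chip glucose-tolerance-test (GTT) measurements
mechanistically, (ii) infer unmeasurable variables such as hepatic insulin
sensitivity and β-cell volume, (iii) predict new culture regimes before
running them, and (iv) rescale chip results to human proportions.

## The model

Two well-mixed medium compartments (liver, pancreas) are connected in a
closed loop with flow rate *Q*. The fast component tracks glucose and
insulin amounts between media exchanges:

    dNG_liver/dt    = G_d(t) + V_hep·EGP − V_hep·(E_G0 + S_I(t)·I_liver)·G_liver
                      + Q·(G_pancreas − G_liver)
    dNG_pancreas/dt = Q·(G_liver − G_pancreas)
    dNI_pancreas/dt = V_β(t)·σ(t)·G_pancreas² / (EC50_I² + G_pancreas²)
                      + Q·(I_liver − I_pancreas)
    dNI_liver/dt    = −CL_I·V_hep·I_liver + Q·(I_pancreas − I_liver)

with glucose dosing *G_d(t)* handled as discrete media-exchange events and
EGP (endogenous glucose production) zero by default. The slow component
describes disease progression over the 15-day culture:

    σ(t)      = σ_max·(1 − t²/(α + t²))                 (secretion-capacity decay)
    S_I(t)    = S_I0·(1 − Imax_Si·G_int/(EC50_Si + G_int))   (insulin resistance)
    dG_int/dt = max(0, G_liver − G_normo)               (excess-glucose integral)
    dG_slow/dt = (G_pancreas − G_slow)/τ_slow           (daily-average glucose)
    dV_β/dt   = k_v·(−d0 + r1·G_slow − r2·G_slow²)·V_β  (β-cell adaptation)

The β-cell net growth rate is bell-shaped in long-term glucose (Topp-type
β-cell mass dynamics): zero at 5.55 and 13.87 mM, positive in between.

Calibration minimizes the SEM-weighted least-squares cost
V(p) = Σᵢ Σₜ (yᵢ(t) − ŷᵢ(t,p))²/SEMᵢ(t)² with a simulated-annealing search
plus Nelder–Mead polish, gates the fit with a χ² test at significance 0.05
(df = number of data points), and collects every visited parameter vector
below the χ² bound into an acceptable set used for uncertainty envelopes.

## Worked example

```bash
python examples/01_simulate_gtt.py
```

prints the pooled GTT samples of a 15-day hyperglycemic co-culture:

```
time_h  observable  pooled value
    24  glucose        11.00
    32  glucose         9.94
    48  glucose         7.36
    72  glucose         4.72
   312  glucose        11.00
   320  glucose        10.21
   336  glucose         8.62
   360  glucose         6.58
   ...
S_I decline over culture : 61.0 %
sigma decline            : 81.2 %
beta-cell volume change  : +21.8 %
```

Eight hours into the day-1 GTT pooled glucose has fallen to 9.94 mM, but
only to 10.21 mM on day 13: glucose tolerance declines over the culture.
The mechanistic readout shows why: cumulative hyperglycemic exposure has
cut hepatic insulin sensitivity by 61% and the per-volume secretion
capacity of the β cells by 81%, only partly offset by a 22% increase in
β-cell volume.

The other examples calibrate against synthetic data with known ground
truth (`02`), predict the hypoglycemic regime's day-13 GTT with a
±0.85 mM dose-uncertainty band (`03`), and rescale the model to human
proportions, where the same glucose load resolves in ~1–2 h instead of
~2 days (`04`). A thin CLI wraps the same operations
(`isletchip generate|simulate|calibrate|predict|translate|recover`).

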