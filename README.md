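# trackmel

Simulation and analysis toolkit for **modulation-enhanced 3D single-molecule
tracking**: localizing and following one fluorophore in real time by firing a
sequence of structured excitation shots at it and comparing the photon counts
against the known excitation profile. The package is aimed at microscopy
method developers and quantitative cell biologists who want to study the
statistical behavior of such a tracker — resolution versus photon budget,
feedback stability, diffusion estimation, state segmentation — without the
optical hardware.

## What it implements

**Engineered excitation PSF and tracking pattern.** The excitation profile is
a single PSF made of three Gaussian foci on the perimeter of a 2 µm circle,
one in focus and two shifted ±400 nm axially. Selecting a focus and steering
it laterally produces a 13-point xy pattern on each of three z-planes; with
one blank repositioning slot per plane change this gives 42 slots of 20 µs
(50 kHz pulse rate), i.e. a 0.84 ms pattern period covering a
950 × 950 × 1390 nm³ volume.

**Cross-entropy MAP localization.** With Poisson emission, the expected count
of shot *i* is λᵢ = c · Φ(r − rᵢ), where c is the fluorophore photon
efficiency. Profiling out c, the negative log-likelihood of a position r
reduces to the cross-entropy between count ratios and PSF ratios:

    l(r) = − Σᵢ nᵢ ln( Φᵢ(r) / Σᵢ Φᵢ(r) )

The estimate minimizes l plus three weak priors — a binary bound T_c on the
implied photon efficiency, a Gaussian prior G_c around an exponentially
weighted mean of past efficiencies, and a Gaussian jump prior G_r around an
exponentially weighted mean of past positions (a 470 nm FWHM at 0.84 ms caps
observable diffusion at ≈ 24 µm²/s). An exponential moving average over
successive likelihood grids trades temporal bandwidth for precision. A
numerical Cramér–Rao bound (Fisher information of the ratio likelihood)
provides the resolution floor.

**Closed-loop simulation.** Emitters follow deterministic stage paths or
state-switching Brownian motion inside a spherocylindrical bacterial cell;
photons are drawn per 20 µs slot (motion blur at single-shot granularity);
a photon-weighted centroid over a two-pattern sliding window drives a PI
controller that re-centers the pattern, standing in for the instrument's
FPGA/piezo loop.

**Diffusion estimation.** The generalized displacement covariance at time lag
j (with blur factor R = (1/Δt)∫S(1−S)dt and localization error σ) motivates
the extended covariance estimator ECVE: D̃ = ⟨Δ_{k,j}Δ_{k+1,j}⟩ / (2Δt(j−1)),
whose defining band is independent of σ; σ itself is then recovered from the
diagonal. The single-step CVE and the MSD are included as comparators.

**Diffusion-state HMM.** Sliding-window ECVE series are segmented with a
K-state hidden Markov model with inverse-gamma emissions, fitted by
Baum–Welch EM (exact M-step via the digamma equation), decoded by Viterbi,
with bootstrap-over-trajectories standard errors.

## Worked example

Track a simulated emitter circling at 0.75 µm radius (0.5 µm axial
peak-to-peak) for 1 s at a 60 kHz mean photon rate, then reconstruct:

```python
from trackmel.config import RunConfig
from trackmel.pipeline import run_pipeline

report = run_pipeline(RunConfig(), seed=1)
print(report.tracking[["sd_x_nm", "sd_y_nm", "sd_z_nm", "n_localizations"]])
```

prints

```
     sd_x_nm    sd_y_nm   sd_z_nm  n_localizations
0  25.672113  26.400457  46.76388             1190
```

i.e. 1190 localizations at 0.84 ms time resolution with ≈ 26 nm lateral and
≈ 47 nm axial error SD against ground truth — the information limit of the
default synthetic three-Gaussian PSF at ~50 photons per pattern (the
numerical CRLB at the pattern center is 29/28/47 nm). A real instrument's
measured PSF is broader and aberrated, so measured resolutions are worse
than this ideal-optics figure.

The same pipeline in cell mode simulates state-switching diffusion
(0.1 / 1.4 / 6 µm²/s with a short-lived intermediate) in an *E. coli*-like
geometry, runs ECVE (j = 8, 16-point windows) and fits the 3-state
inverse-gamma HMM:

```bash
trackmel pipeline --mode cell --seed 1 --set simulation.n_trajectories=30 --no-bootstrap
```

The fitted slow state lands near its ground truth while the nominal fast
state sits *between* the intermediate and fast truth values — the
intermediate state is too short-lived to resolve at the estimator's time
base and mixes into the fast state.

Other entry points: `trackmel psf build|inspect`, `trackmel pattern`,
`trackmel simulate-track`, `trackmel localize`, `trackmel diffusion`,
`trackmel hmm`, `trackmel benchmark-resolution` (resolution vs effective
photon rate via likelihood tail averaging).

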