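# hpr — model-based analysis of fear-conditioned heart period responses

Cued fear conditioning pairs a neutral stimulus (CS+) with an aversive
event (US); a second stimulus (CS−) is never paired. In humans the
conditioned response includes a parasympathetically mediated slowing of
the heart — fear bradycardia — visible as a transient lengthening of
the interbeat interval after CS onset. `hpr` quantifies this response
for researchers who want a fear-memory index from ECG or
pulse-oximetry recordings: it turns raw cardiac signals into heartbeat
times, a continuous heart-period series, and amplitude estimates of
the autonomic input driving the response, and it compares scoring
methods by their ability to discriminate CS+ from CS−.

## The model

The heart-period response (HPR) is treated as the output of a linear
time-invariant system: an impulse of autonomic input at CS onset,
convolved with a canonical heart period response function (HPRF). The
HPRF is a gamma density

$$h(x) = \frac{A}{\theta^{k}\,\Gamma(k)}\,(x-x_0)^{k-1}\,e^{-(x-x_0)/\theta}$$

with shape $k$, scale $\theta$, onset $x_0$; the default parameters
($k=48.5$, $\theta=0.182$, $x_0=-3.86$) peak 4.79 s after CS onset.
Per subject, the 10 Hz band-pass-filtered heart-period series $Y$ is
modelled with a GLM, $Y = X\beta + \varepsilon$, whose columns are
impulse trains at the CS+ / CS− onsets convolved with the basis set —
model G2 uses the canonical HPRF plus its time derivative, which
absorbs between-subject peak-latency variation. $\beta$ is estimated
with the Moore–Penrose pseudoinverse. A condition's score is the
signed maximal deviation of the reconstructed response 2–11 s after
CS onset.

Predictive validity of any scoring method (model-based G1/G2/G3/S1 or
peak-scoring P1/P2/P3) is the evidence of a regression of condition
(CS+ = 1, CS− = 0) on score with subject intercepts, summarised as
$\mathrm{NLL} = n\log(\mathrm{RSS}/n)$; an absolute NLL difference
above 3 between methods is decisive, and the regression's t statistic
equals the paired t across subjects.

A fully seeded synthetic-session generator (beat trains, trial
schedules with 7/9/11 s ITIs and 50% reinforcement, respiratory sinus
arrhythmia, drift, gamma-shaped conditioned responses) makes the whole
pipeline testable offline with known ground truth.

## Worked example

```python
from hpr import SimConfig, simulate_study, PipelineConfig, run_study

sessions = simulate_study(SimConfig(n_subjects=10, seed=42))
result = run_study(sessions, PipelineConfig())
for m, e in sorted(result.evidence.items(), key=lambda kv: kv[1].nll):
    print(f"{m:3s}  NLL={e.nll:8.1f}  t={e.t_stat:6.2f}  p={e.p_value:.2g}")
```

prints

```
G2   NLL=  -133.3  t= 41.93  p=1.2e-11
G3   NLL=  -125.0  t= 34.04  p=8e-11
G1   NLL=  -123.1  t= 32.38  p=1.3e-10
P3   NLL=  -120.6  t= 30.43  p=2.2e-10
S1   NLL=  -117.3  t= 28.03  p=4.6e-10
P1   NLL=  -114.4  t= 26.04  p=8.8e-10
P2   NLL=  -102.8  t= 19.37  p=1.2e-08
```

Smaller NLL means better CS+/CS− discrimination: here model G2
(canonical HPRF + derivative) wins decisively over every alternative
(its margin over G1 is 10.2 > 3), and every method detects the
conditioned difference (all p ≪ .05) — the sessions were simulated
with a true 30 ms CS+/CS− amplitude difference, so this is the
expected outcome. `result.scores` holds the per-subject,
per-condition scores in ms; `result.comparisons` the pairwise ΔNLL
verdicts.

The same analysis is available from the shell:

```
hpr simulate --seed 42 --subjects 10 --out study/
hpr evidence --study study/ --out results/
```

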