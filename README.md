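# burstclass

Behaviour classification from burst-mode tri-axial accelerometry, for
movement ecologists who need to infer what a free-ranging animal is doing
from a collar that records a few seconds of acceleration every couple of
minutes — and who cannot observe the animal to check.

## The problem and the method

Animal-borne accelerometers are usually ground-truthed on observable
(captive) individuals: each short recording interval (a **burst**; here 110
samples per axis at 33.33 Hz ≈ 3.3 s, every 2 min) is paired with a
behaviour from a fixed ethogram (feeding, grooming, resting, caching,
trotting, walking). A classifier trained on those bursts is then transferred
to wild conspecifics. Burst data are scarce, so the package augments them
with a **moving window**: every contiguous sub-window of length *w* (step 1)
of a burst becomes a training example — a length-110 burst at *w* = 79
yields 110 − 79 + 1 = 32 order-preserving sub-samples.

Each window is summarized by a fixed predictor set: per-axis mean, sd,
inverse coefficient of variation (x̄/s), variance, skewness and kurtosis;
the combined statistics q = mean‖(x,y,z)‖, pitch and roll (posture angles
from the static, window-mean acceleration), ODBA (overall dynamic body
acceleration, Σ<sub>axes</sub> mean|a − ā|); and the whole one-sided FFT
magnitude spectrum of each axis — 142 predictors at *w* = 79.

Three back-ends train on these tables: a radial-kernel SVM, a 500-tree
random forest, and a feed-forward neural network (one hidden rectifier
layer, softmax output). At prediction time a window is assigned its best
class only if its probability strictly exceeds a threshold τ (default 0.7
for the network), otherwise the rejection class **"other"** — which absorbs
behaviours the captive animals never showed and mixed-behaviour bursts. The
burst's final class is the absolute majority (> 50 %) over its 32 window
classes, with no majority again mapping to "other".

The window size is selected by sweeping *w*, scoring each as
mean(mean recall, mean precision, 1 − proportion "other"), smoothing the
curve with a penalized cubic spline (basis dimension 40, GCV), and taking
the smallest window whose fitted score is at the plateau (difference-quotient
slope ≈ 0).

Because wild predictions cannot be checked directly, four indirect
validation procedures interrogate the classified stream: diel composition
by month and time of day; coherence with GPS clusters (maximal runs of
consecutive fixes within 50 m of the run's first fix, counting only
clusters holding ≥ 10 classified bursts); coherence of behaviour with
GPS-derived speed (bursts within 10 s of a fix; one-sided Wilcoxon
rank-sum, resting vs trotting); and day × time-of-day actograms of ODBA or
a behaviour indicator with sunrise/sunset overlays.

No public dataset accompanies this workflow, so `burstclass.synthetic`
generates the whole study design with known ground truth: a captive
training set with realistic class imbalance (2114 resting … 162 walking
bursts, 4159 total) and a multi-day "wild" deployment with a
nocturnal-crepuscular activity schedule, bout persistence, and GPS tracks
that dwell within < 50 m during rest.

## Worked example

```python
import burstclass as bc

captive = bc.generate_captive_dataset(seed=0)          # 4159 labelled bursts
clf = bc.BurstClassifier(kind="ann", window_size=79, tau=0.7,
                         max_iter=30, random_state=0).fit(captive)

scenario = bc.WildScenario(days=7, seed=1)
wild, fixes, truth = bc.generate_wild_track(scenario)  # truth is withheld
records = clf.predict_records(wild)

pred = {r.burst_id: r.burst_class for r in records}
report = bc.performance_report(truth["behaviour"],
                               [pred[b] for b in truth["burst_id"]])
print(f"burst-level kappa: {report.kappa:.3f}")

clusters = bc.segment_clusters(fixes, radius_m=50)
coh = bc.cluster_behaviour_coherence(records, clusters, min_items=10)
print(f"in-cluster: resting {coh['resting']:.2f}, trotting {coh['trotting']:.2f}")
```

Output:

```
burst-level kappa: 1.000
in-cluster: resting 0.97, trotting 0.02
```

A kappa of 1.0 means every one of the 5040 wild bursts was assigned its
true behaviour (the synthetic classes are cleanly separable — see
`docs/methods.md` for what this does and does not demonstrate). The cluster
proportions reproduce the expected signature: resting happens almost
entirely inside stationary GPS clusters, trotting almost never.

The same pipeline is scriptable from a shell:

```sh
burstclass simulate captive --seed 0 --out data/captive
burstclass train --data data/captive --model ann --window 79 --tau 0.7 --out run/
burstclass simulate wild --days 7 --seed 1 --out data/wild
burstclass predict --data data/wild --model run/model.pkl --out run/
burstclass validate --gps data/wild/gps.csv --pred run/predictions.csv --out run/
```

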