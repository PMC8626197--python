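# Methods

## Model and assumptions

A patient's stream of vital-sign records is modelled as draws from a small
number of dense regions in feature space — the physiological states the
patient occupies — contaminated by sporadic aberrant readings caused by
sensor or transmission faults. Each record maps to a point whose
coordinates are the raw measured values (systolic and diastolic pressure
in mmHg, temperature in °C, pulse in beats/min); acquisition time is
metadata only. Under this model, anomaly detection reduces to density
clustering: DBSCAN labels every point core, border or noise, and the noise
points are the anomalies. No distributional form is assumed beyond "dense
regions are much denser than the contamination"; clusters may have any
shape.

The clustering dialect is fixed throughout: Euclidean distance, closed-ball
neighbourhoods that include the query point, a point is core when its
ε-ball holds at least MinPts points, and border points reachable from
several clusters go to the cluster whose expansion reaches them first
under an ascending-id scan. These conventions match the dominant DBSCAN
dialect (and scikit-learn's, which the tests use as an independent
oracle), and fixing them makes every run order-independent and exactly
reproducible.

## Partitioned clustering and merging

Large or distribution-split data are processed as consecutive slabs along
the first coordinate, each clustered locally with its own radius ε_i.
Slab cuts fall at equal-count boundaries (midpoints between adjacent order
statistics), the simplest scheme that respects the data distribution.
Stitching distinguishes two boundary regimes:

* **With an overlap zone** (points within `overlap_width` of the cut
  belong to both slabs, default half-width `max ε_i` so the zone spans one
  neighbourhood on each side), every shared point was clustered twice and
  its role pair decides: core on either side ⇒ the two clusters merge;
  border on both ⇒ the point may join either cluster — resolved to the
  lower `(partition, cluster)` key purely for reproducibility, since the
  criterion itself is indifferent; member/noise ⇒ it joins its cluster;
  noise/noise ⇒ noise for the whole boundary region.
* **Without an overlap zone** (`overlap_width = 0`), clusters are compared
  through their boundary-object sets — members within ε_i of the cut
  plane. Two clusters merge when the mean over all cross pairs of
  distances does not exceed `min(ε_i, ε_{i+1})`; the denominator is the
  full product `|E_A|·|E_B|`, i.e. an unweighted mean of every cross pair.
  A residual noise point near the cut is absorbed into a neighbouring
  class when its mean distance to that class's boundary set is within the
  absorbing slab's radius; absorption is attempted in both directions
  across each cut and, among several candidate classes, in ascending
  cluster-key order (first hit wins) for determinism. Because a mean is
  bounded below by its smallest term, a point farther than ε from every
  boundary member can never be absorbed.

Merge verdicts accumulate in a union-find, so merging is an equivalence
closure and final labels are constant within each merged class. Residual
noise is then pooled and clustered once more with `eps = min_i ε_i` and
the global MinPts — the conservative choice: a class that re-emerges from
pooled noise must satisfy the strictest local density demand. Final labels
are dense integers ordered by each class's smallest core id
(partition-derived classes first, noise-derived after), which makes a
single-partition run reproduce plain DBSCAN *exactly*, labels and roles
included — a reduction law the acceptance suite asserts.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| ε (eps) | 18.0 | feature units (≈ mmHg-dominated) | near the top of the 5-NN distance curve of preset-like data, so virtually all normal readings are density-connected while clinically extreme readings stay isolated |
| MinPts | 5 | points | one more than the 2·dim rule-of-thumb floor for 4-d data; a pair of nearby anomalies can never seed a cluster |
| minpts_scale | 1.5 | — | severe patients: MinPts′ = ⌈MinPts·1.5⌉ demands half again as much evidence per state |
| eps_scale | 0.8 | — | severe patients: ε′ = 0.8·ε tightens reach; both directions only ever grow the flagged set |
| reference ranges | 90–140/120 mmHg systolic, 60–90/80 diastolic, 36.1–37.3/36.8 °C, 60–100/72 bpm | per vital | standard adult resting values (low–high/target) |
| windows | contiguous, equal-length, non-overlapping | — | chronic profiles repeat the full pipeline per window; one window reduces exactly to the unwindowed pipeline |

Feature scaling is off by default — coordinates are the raw measurement
values — because the default ε was chosen on that scale; optional
z-scoring exists for analyses that want to even out the vitals'
variances (a constant column is then a hard error, not a silent skip).

The deviation value of a vital is the *signed* difference between the
representative and the range target; the representative is the per-vital
mean of the largest retained cluster, on the view that the largest dense
region reflects the patient's dominant physiological state. Diagnosis is
threshold crossing of the reference ranges only — no disease ontology is
attempted.

## Synthetic data: what it emulates and what it does not

The generator draws each cluster's vitals from independent normals around
a preset mean (120±8 / 80±6 mmHg, 36.8±0.3 °C, 72±6 bpm — plausible
stable-adult values), uniform timestamps over 24 h, and anomalies
rejection-sampled to sit at least `anomaly_offset` (default 60 feature
units) from every cluster mean; the separation is asserted at generation
time and all draws flow from one integer seed. `generate_partitioned`
additionally plants a sparse cluster straddling a stated cut with fewer
than MinPts members per side, guaranteeing the noise-re-clustering path is
exercised.

Real vital-sign streams have features the generator deliberately omits:
circadian and activity-driven drift, correlated vitals, heteroscedastic
sensor error, missingness bursts. Passing tests therefore demonstrate the
algorithmic contracts (recovery of planted structure under stated
separations), not clinical performance on hospital data.

The default experiment sizes — 120 normal readings plus 6 anomalies per
dataset, 20 seeds for recovery rates, 100 random instances for oracle
equivalence — were fixed once, ahead of testing, as the smallest sizes at
which the quantities of interest are stable; the whole suite runs in a few
seconds.

## Numerical choices and degenerate inputs

* Pairwise neighbourhoods use an exact O(n²) scan; at desk scale this is
  faster and simpler than a spatial index and removes a source of
  implementation-dependent tie behaviour.
* Neighbourhood membership compares `sqrt(d²) ≤ ε` (not squared), matching
  the oracle implementation's boundary handling bit for bit.
* Mean-distance statistics are computed with `scipy.spatial.distance.cdist`
  and agree with explicit double/single loops to 1e-12 (asserted).
* Relative error keeps full precision internally and rounds half-up to one
  decimal only for display, so 5.48 and 5.53 both display as 5.5.
* Empty datasets, empty boundary sets (the mean is undefined), a
  nominal value of zero, and more partitions than points are input errors;
  an all-noise clustering is a warning with an empty retained set, and a
  window with fewer than MinPts records is flagged insufficient rather
  than failing the analysis.
* One tabulated row of the built-in reference error table is internally
  inconsistent (its pair recomputes to 6.9% where 6.5% is printed); the
  table is kept verbatim and the discrepancy is pinned by a test rather
  than silently corrected. The mean error is 5.5% either way.

## Known limitations

* The partitioning axis is fixed to the first coordinate and cuts are one
  dimensional; multi-axis or learned partitions are out of scope.
* ε must be supplied or defaulted; no automatic k-distance elbow selection
  is provided.
* The "comprehensive physiological characteristic value" summarised by
  `centroid_predict` is an abstract scalar; the stand-in predictor is the
  mean of the dominant cluster's first coordinate and is labelled as such.
* Border-point assignment between adjacent clusters is convention, not
  inference; only core/noise status is convention-free.
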