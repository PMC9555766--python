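# sprintcoord

Segment-coordination analysis for initial sprint acceleration from
sagittal-plane segment angle time series: modified vector coding with an
eight-bin coordination classification and segment dominancy, circular group
statistics, step-to-step similarity scoring (CA_Diff), and a repeated-measures
inferential layer — plus a synthetic sprint-kinematics generator so the whole
pipeline is testable and reproducible without any external data.

## What it computes

1. **Preprocessing** — zero-phase Butterworth low-pass filtering (default
   15 Hz, order 4), segmentation of a trial into *steps* (one toe-off to the
   next contralateral toe-off, starting at front-foot block clearance
   `TO_0`), leading/trailing limb-role assignment (the swing leg at the
   opening toe-off leads; roles alternate each step), flight/contact times,
   and linear time normalization of every step to 101 points.
2. **Vector coding** — the coupling angle γ ∈ [0°, 360°) between adjacent
   points of the proximal-vs-distal angle-angle plot; classification into
   eight 45° coordination bins (in-/anti-phase × rotation direction ×
   dominant segment); segment dominancy via the gradian conversion
   (γ folded into a quadrant × 100/90), constrained to [50%, 100%].
   Couplings: thigh–thigh (proximal = trailing thigh), trunk–shank and
   shank–foot (intra-limb couplings use the stance = leading limb).
3. **Group statistics** — pointwise circular mean profiles and
   between-individual circular SD (angular deviation √(2(1−r)) by default,
   √(−2 ln r) selectable), per-step bin frequencies, and the CA_Diff score:
   per-interval bin-ring distances (0–4) summed over the step as a
   percentage of the maximum.
4. **Inference** — one-way repeated-measures ANOVA with Mauchly's
   sphericity test and Greenhouse–Geisser correction (partial η² effect
   size), Friedman tests (optionally exact by permutation for small n),
   Wilcoxon signed-rank pairwise tests (exact for n ≤ 25) and Bonferroni
   adjustment; touchdown/toe-off discrete kinematics extraction.
5. **Simulation** — event-annotated seven-segment cohorts with known
   coordination ground truth (anti-phase thighs with an exact trailing/
   leading slope ratio, trunk reversal at touchdown, early-stance
   dorsiflexion dip, band-limited noise, per-participant jitter).

## Conventions

- Angles are in **degrees**, anticlockwise-positive as viewed from the
  athlete's right with motion left-to-right; clockwise rotation decreases
  the angle. Trunk/shank are measured from the forward horizontal (vertical
  = 90°); the foot is 0° when flat, negative when plantarflexed.
- Time is **seconds from recording start**; events carry times, not frames.
- Derived joint angles: hip = trunk − thigh, knee = thigh − shank,
  ankle = shank − foot (dorsiflexion decreases the ankle angle).
- Files: angle CSV (`time_s` + `trunk, thigh_L, thigh_R, shank_L, shank_R,
  foot_L, foot_R`), events CSV/JSON (`kind, time_s, side, label`), YAML
  analysis config. Comma-separated, `.` decimal, UTF-8, one header row.

## CLI

```sh
# generate a synthetic cohort (angle/event CSVs + manifest.json)
sprintcoord simulate --out cohort/ --seed 1 --participants 21

# coordination profiles, bin frequencies, CA_Diff, group profiles
sprintcoord analyze --in cohort/ --out analysis/ --coupling all

# RM-ANOVA / Friedman / Wilcoxon reports from the analysis tables
sprintcoord stats --in analysis/ --out stats/

# figures: per-step bar profiles (height = dominancy, colour = bin,
# shaded stance), group mean + SD panels, SD curves, bin-frequency tables
sprintcoord plot --in cohort/ --out figs/ --kind group --coupling thigh_thigh
```

`sprintcoord <cmd> --help` lists all flags; analysis parameters
(normalization length, filter cutoff/order, circular SD formula, bin
boundary tie rule) are overridable via `--config config.yaml`.

## Layout

```
src/sprintcoord/
  io.py             domain types, trial/profile/config I/O
  preprocessing.py  filtering, step segmentation, limb roles, normalization
  vector_coding.py  coupling angle, 8-bin classification, dominancy
  coordstats.py     circular statistics, bin frequencies, CA_Diff
  inference.py      RM-ANOVA/GG, Friedman, Wilcoxon, Bonferroni, reports
  simulate.py       synthetic cohort generator with ground truth
  analysis.py       cohort orchestration
  viz.py, cli.py    figures and command-line entry points
```
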