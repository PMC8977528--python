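# salpinx

Quantitative histology of the fallopian tube: stromal texture panels and
epithelial run-length topology.

Serous tubal intraepithelial carcinoma (STIC) — the microscopic
fallopian-tube precursor of high-grade serous ovarian cancer — is hard to
find and subjectively diagnosed. `salpinx` implements two computational
readouts of ordinary H&E sections that carry signal about a tube's STIC
status, for pathology-imaging researchers who have tiles and classified
cell sequences and want reproducible statistics:

* **Stromal texture panel.** Each stromal tile is color-normalized
  (Reinhard, CIELAB), deconvolved into hematoxylin and eosin
  optical-density channels (Beer–Lambert, Ruifrok–Johnston vectors), and
  described by 45 SFTA + 256 LPQ + 256 BSIF features per channel —
  **1114 features** per tile (557 per stain). Tile features aggregate to
  case-level medians, are z-scored, and screened with per-feature one-way
  ANOVA at the Bonferroni threshold α = 0.05/1114 ≈ 4.49×10⁻⁵, followed
  by Tukey–Kramer comparisons between the four stromal groups (Benign,
  NoSTIC, AwaySTIC, NearSTIC) and a seeded 2-D UMAP embedding.
* **Epithelial topology.** Ordered secretory/ciliated label sequences
  along monolayer ROIs are scanned for maximal runs; a secretory (ciliated)
  cell expansion — SCE (CCE) — is a run of **more than 10** cells of one
  type. Per-slide summaries (counts, relative numbers = count/total cells,
  mean expansion sizes) feed Kruskal–Wallis / Mann–Whitney group
  comparisons, Spearman age correlations, confounder-adjusted log-linear
  regression, and ROC analysis (rank-based AUC, DeLong 95% CI, Youden
  optimal cutoff) of STIC vs pooled Benign+NoSTIC.
* **Synthetic cohorts.** A first-class generator produces both data
  streams with known ground truth: Markov-chain epithelium (geometric run
  lengths, age/STIC acting on persistence logits) and Gaussian-random-field
  H&E tiles rendered through the same stain model, with graded per-group
  texture effects.

See `docs/methods.md` for models, parameters and limitations.

## Worked example

Simulate the default study design (39/13/25 fimbria cases), summarize
expansions, and evaluate the mean-cells-in-SCE biomarker:

```python
from salpinx.simulate import CohortConfig, simulate_cohort
from salpinx.topology import ROISequence, SlideEpithelium, summarize_slide, summaries_frame
from salpinx.biomarker import roc_analysis, spearman_corr

config = CohortConfig(tile_cases={"Benign": 2, "NoSTIC": 2, "STIC": 2}, render_tiles=False)
_, cells, covariates, _ = simulate_cohort(config, seed=1)

slides = []
for (cid, region, group), sub in cells.groupby(["case_id", "region", "group"]):
    rois = tuple(ROISequence(str(r), tuple(df.sort_values("position").cell_type))
                 for r, df in sub.groupby("roi_id"))
    slides.append(SlideEpithelium(cid, region, group, rois))
df = summaries_frame(summarize_slide(s) for s in slides)

print(df.groupby("group")[["relative_sce", "mean_cells_in_sce"]].mean().round(4))
curve = roc_analysis(df.mean_cells_in_sce, (df.group == "STIC").astype(int))
print(f"AUC {curve.auc:.3f}  CI {curve.ci95}  cutoff {curve.optimal_cutoff:.2f}")
```

prints

```
        relative_sce  mean_cells_in_sce
group
Benign        0.0091            14.2290
NoSTIC        0.0063            14.1166
STIC          0.0262            21.9255
AUC 0.996  CI (0.988, 1.000)  cutoff 16.85
```

STIC slides carry more and longer secretory expansions; the ROC stage
recovers an operating cutoff (16.9 cells per SCE here) close to the
generator's decision boundary of 15, with near-perfect separation at the
generator's default effect size. Adding the age linkage, Spearman
correlation between age and relative SCE on the same cohort gives
rho = 0.44, p = 7.7e-5.

The same pipeline is available from the shell:

```bash
salpinx simulate --outdir data/ --seed 1 --tile-size 64
salpinx extract-features --manifest data/manifest.csv --out features.csv
salpinx cohort-stats --features features.csv --out screen.json --umap umap.csv
salpinx summarize --cells data/cells.csv --covariates data/covariates.csv --out summaries.csv
salpinx roc --summaries summaries.csv --metric mean_cells_in_sce --region fimbria --out roc.json
```

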