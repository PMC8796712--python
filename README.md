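# zooscankit

Zooplankton community analysis from ZooScan/EcoTaxa-style object tables:
standardized abundance, biovolume and dry-mass biomass per depth stratum;
depth-integrated seasonal and diel summaries; centroid-depth statistics for
diel vertical migration (DVM); SIMPER day–night dissimilarity decomposition;
and permutation-tested redundancy analysis (RDA) against CTD-derived
environmental variables.

It is written for plankton ecologists who work with scanner-based imaging of
stratified net hauls (e.g. closing nets over 0-50-100-200-300-400-450 m in a
deep fjord) and who need the full chain from per-object measurements to
community-level statistics in one tested place. Because raw scan archives are
rarely shareable, the package ships a synthetic-community generator with
known ground truth, so every downstream stage is testable end to end.

## The quantities computed

Each scanned object is reduced to the moment-equivalent ellipse of its binary
silhouette. Its individual volume is the prolate spheroid

    V (mm³) = 4/3 · π · (major/2) · (minor/2)²

and its individual dry mass comes from a taxon-specific allometric
regression on scanned body area A (mm²),

    DM (µg) = a · A^b

with a shipped registry of 23 organism categories (most use a = 43.38,
b = 1.54; Copepoda 43.97/1.52; Chaetognatha 23.45/1.19; Cnidaria 4.03/1.24).
Counts and per-object sums from a scanned subsample are scaled by the binary
split fraction F ∈ {1, 1/2, …, 1/64} and by the volume filtered by the net,

    V_N (m³) = π · (net diameter/2)² · depth interval · filtration efficiency,

giving abundance (n/F)/V_N in ind m⁻³, biovolume (ΣV/F)/V_N in mm³ m⁻³ and
biomass (ΣDM/F)/V_N in mg DM m⁻³. Objects smaller than the scanner's 0.3 mm
equivalent-circular-diameter detection limit are filtered out; members of
multi-object vignettes are counted and assigned their taxon's mean volume and
dry mass.

Vertical structure is summarized by depth integration (Σ value·thickness
over whole strata above 400 m) and the centroid depth

    CD = Σ(p_k · z_k) / Σ p_k

over stratum mid-depths z_k. Day–night CD contrasts use a chi-square
contingency test; taxa driving day–night community differences are ranked by
SIMPER (additive per-taxon decomposition of mean Bray–Curtis dissimilarity,
with the cumulative-70% cutoff). RDA projects log(x+1) abundances onto
column-centred water-column means of temperature, salinity, oxygen and log
chlorophyll-a, and a 10,000-iteration permutation test of the pseudo-F
statistic assesses significance.

## Worked example

```python
from zooscankit import default_comau_community, dry_mass, ellipsoid_volume
from zooscankit.io import RunConfig
from zooscankit.pipeline import run_study

print(ellipsoid_volume(2.0, 1.0))      # 1.047198  (mm³, = π/3)
print(dry_mass("Copepoda", 1.3))       # 65.52     (µg, 43.97·1.3^1.52)

study = run_study(default_comau_community(), RunConfig(seed=1), n_perm=999)
print(study.diel_tests["spring"]["p"])            # 4.99e-14
print(study.simper["spring"].top_taxa[:2])        # ['Cyclopoida', 'Metridinidae']
print(round(study.rda.constrained_fraction, 3))   # 0.163
print(study.rda_permutation.p_value)              # 0.061
```

The study object holds per-sample concentrations, depth-integrated
abundances, and abundance/biovolume centroid depths. For the synthetic
spring event above, the migrator taxon's abundance CD moves from 163 m by
day to 45 m at night — the DVM signal the chi-square contrast detects — and
the spring day/night integrated abundances (ind m⁻²) average, e.g., 2,554
for Cyclopoida and 4,234 for Harpacticoida.

The same pipeline is scriptable from a shell:

```bash
zooscankit generate --seed 1 --out-dir out/        # object tables + CTD casts
zooscankit all --seed 1 --out-dir out/ --n-perm 999
```

which writes `concentrations.csv`, `integrated_abundance.csv`,
`centroid_depths.csv`, per-season `simper_*.csv` and
`analysis_summary.json`.

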