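# CSV schemas

All tables are comma-separated, UTF-8, `.` decimal, header row mandatory.
Readers (`paleotroph.io.read_table`) reject missing required columns and
unknown enum values with messages naming the file and column. The same
definitions are available programmatically as `paleotroph.io.SCHEMAS`.

## teeth.csv — one row per tooth

| column | required | description |
|---|---|---|
| specimen_id | yes | unique tooth identifier |
| species | yes | species name (open nomenclature allowed) |
| genus | yes | genus name |
| epoch | yes | one of: Late Cretaceous, Paleocene, Eocene, Oligocene, Miocene, Pliocene, Modern |
| region | no | broad collecting region label |
| is_piscivore | yes | True for fish-eating baseline taxa |
| preservation | yes | `modern` or `fossil` |
| d15n_eb | yes | enameloid-bound δ15N, ‰ vs. air |
| d15n_dentin | no | dentin collagen δ15N, ‰ vs. air (modern teeth) |
| n_content | no | N content, μmol N/g |
| crown_height | no | crown height, cm |
| tooth_position | no | position label (e.g. U, L, L2, l2) |

Generator output adds ground-truth columns prefixed `true_` (trophic level,
pre-noise δ15N, N content, total length); analysis code never reads them.

## raw_analyses.csv — one row per mass-spectrometric analysis

| column | required | description |
|---|---|---|
| analysis_id | yes | unique analysis identifier |
| batch_id | yes | measurement batch |
| specimen_id | yes | tooth id, or reference/standard name |
| role | yes | sample, nitrate_reference, amino_acid_reference, blank, inhouse_standard |
| measured_d15n | yes | δ15N on the instrument scale, ‰ |
| n_amount | yes | total N in the analysis, nmol |
| dissolved_mass | samples/standards | dissolved enameloid, mg |
| certified_d15n | references | certified δ15N, ‰ vs. air |

## reduced.csv — one row per specimen (reduction output)

specimen_id, batch_id, d15n_eb (‰, calibrated and blank-corrected), sd_d15n
(‰ over replicates, empty if n = 1), n_replicates, n_content (μmol N/g),
blank_fraction (blank share of total N).

## pairs.csv — paired tissues for ground-truthing

specimen_id, d15n_eb (‰), d15n_dentin (‰).

## literature.csv — one row per literature observation

| column | required | description |
|---|---|---|
| group | yes | `shark` or `marine_mammal` |
| family | yes | taxonomic family |
| species | no | species name |
| tissue | no | tissue type |
| mean_d15n | yes | observation mean δ15N, ‰ vs. air |
| sd_d15n | no | observation SD, ‰ (empty when n = 1) |
| n_individuals | yes | individuals behind the observation (≥ 1) |

## length_functions.csv — crown-height → total-length coefficients

position_class, slope (m per cm), intercept (m), source (provenance tag;
the shipped defaults are `synthetic-placeholder`).
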