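# Methods

## The exposure model

`smokedays` estimates *potential* population exposure to wildfire smoke: an
indicator of smoke overhead, not a ground-level concentration. The inputs
are (a) daily HMS Smoke plume polygons, drawn by NOAA analysts from
satellite visible imagery and tagged light / medium / heavy from GOES
aerosol optical depth, and (b) block-group centers of population, the
Census "balance point" of where each unit's residents live. Using a single
representative point per block group — rather than its boundary polygon —
keeps the daily intersection a pure point-in-polygon problem and reduces
misclassification in sparsely populated units, at the cost of an all-or-
nothing assignment per block group.

Because one day's smoke layer is assembled from several satellite passes,
the same location can sit under many plumes. Days are therefore
**flattened**: a point is covered at a density iff any plume of that density
from any pass contains it. The package never computes a geometric
union/dissolve — the coverage keeps the raw polygon set and ORs per-point
containment, which has identical observable semantics, avoids robustness
failures on sloppy plume rings, and keeps the brute-force test oracle
trivial. Flattening is consequently idempotent and invariant to plume input
order (both property-tested).

### Containment

Containment is evaluated directly on the lon/lat plane (no projection),
matching the scale of the problem: plumes span degrees while the point set
is fixed, and a planar treatment at HMS latitudes does not change which
points fall under which plumes in practice. The predicate is the even-odd
(ray-crossing) rule with crossing parity accumulated over **all** rings of a
polygon, so nested rings behave as holes and self-intersecting outlines
follow the even-odd fill without any geometry repair or mutation of source
data. Points exactly on an edge or vertex count as **inside** — a
deterministic, orientation-independent convention that biases toward
exposure, the conservative direction for public health. Vertex crossings
are handled with the half-open rule on the y-interval, so parity is counted
once per true crossing; the boundary test itself is exact (zero cross
product within the segment's box). The per-density bounding-box prefilter is
an optimization only and is tested to be observationally identical to the
naive scan. Antimeridian-crossing plumes are not specially handled (HMS
covers North America); this is a known limitation.

## Input handling

**HMS files.** The density attribute's column name and encoding drift
across archive years, so the reader probes an ordered candidate list
(default `Density`, `density`) and normalizes case-insensitive string labels
(`light`/`medium`/`heavy`, with `dense` ≡ heavy) as well as the numeric
codes 5/16/27 in any decimal rendering. An unrecognized label is a hard
error by default — silent misclassification corrupts exposure counts — with
an explicit skip-and-log mode for bulk runs. Features whose every ring has
fewer than three distinct vertices are dropped with a logged count. A
missing archive day is a distinct condition (`DayAbsentError`) from a
present day with zero plumes (empty table). Several per-pass files for one
day are read and concatenated before flattening. Since no shapefile library
is part of the runtime environment, the package carries its own minimal
reader/writer for the HMS dialect (polygon and null shapes, dBASE C/N
fields, zipped sets); round-trip identity is tested.

**Census points.** FIPS components are kept internally as zero-padded text
(`"01"` ≠ `1`); the published exposure schema declares them integers, so the
CSV writer emits bare integers and the reader restores the padding by
component width. Duplicate FIPS keys and missing columns are hard errors;
coordinates tolerate the explicit `+` signs of the Census file.

## Output schema

One CSV per day named `<yyyymmdd>.csv`, header exactly
`date,STATEFP,COUNTYFP,TRACTCE,BLKGRPCE,POPULATION,light,medium,heavy`,
UTF-8, Unix newlines. Only smoke-present rows are written; a processed day
with no smoke yields a header-only file, distinguishing it from an absent
archive day (no file, counted in the run summary). A dense mode emitting
every point (all-zero rows included) exists behind a flag; re-filtering a
dense table recovers the sparse one exactly. Output bytes are deterministic:
records are sorted by GEOID, so re-runs and plume re-orderings are
byte-identical. A day present in the archive but failing mid-parse is
recorded in the run summary without aborting the range.

## Metrics

* **Person-days** (Σ indicator × population) are reported per density
  category separately, never summed across categories. Groups are any
  subset of date/state/county/tract keys.
* **Exposed-population series** is person-days grouped by date. The
  default series is *non-exclusive* (a light+heavy person appears in both
  the light and heavy series, mirroring per-category indicator sums); an
  *exclusive* variant counting each person once at their maximum density is
  also provided — the exclusive series over the three levels partitions the
  exposed population, which is tested.
* **County density days** count distinct calendar dates (never rows) on
  which any block group of the county carries the indicator — the county
  inherits its worst block group.
* **Population-weighted density** maps each block group to its maximum
  numeric level (none=0, light=1, medium=2, heavy=3) and weights by its
  share of county population. Exposure files retain only smoke-present
  rows, so this metric takes the full population table as a separate input;
  unexposed block groups enter at level 0, and the block-group populations
  are taken from that authoritative table, not from the exposure rows. A
  county with zero total population is reported as missing (NaN). An
  exposure row referencing a block group absent from the population table is
  an error (inconsistent inputs). By default the county×day grid covers the
  dates present in the exposure table; an explicit date list extends it
  (days with no exposure score 0).

## Synthetic scenarios

The generator stands in for the NOAA archive and the Census file so the
whole pipeline runs offline with a known answer. Defaults: points uniform on
a lon/lat box loosely covering the western US (−125…−102°E, 32…49°N, where
most HMS smoke sits); block-group populations lognormal with median ≈ 1200
persons and σ = 1 on the log scale, the right-skewed shape of real
block-group counts; county assignment Zipf-skewed across 8 synthetic
counties so partitions mix dense and sparse counties and weighted-density
tests see nontrivial population shares; 3/2/2 light/medium/heavy plumes per
day with radii of 1–6 degrees — enough overlap that multi-density and
multi-plume cases occur routinely. Plumes are simple convex k-gons (5–12
vertices) by default, for which containment is unambiguous; a `concave`
option substitutes star-shaped polygons to exercise the even-odd rule. Raw
density labels are drawn from the archive's label variants, including
`Dense` and the numeric codes. Everything is keyed to a single seed:
identical seed and spec give byte-identical files and ground truth, and
derived per-day seeds stay below 2³¹.

The ground-truth table is computed by an independent route — a brute-force
double loop over points and plumes using shapely's boundary-inclusive
`covers` — sharing no geometry code with the coverage/exposure modules, so
pipeline-versus-truth comparisons are a genuine two-implementation check.
For the simple (convex or star-shaped, single-ring) polygons the generator
emits, shapely's containment and the package's even-odd rule agree
everywhere except possibly exactly on boundaries, which random points hit
with probability zero; boundary behavior is pinned separately with
hand-placed points.

What passing synthetic tests does **not** show: fidelity on real HMS
geometries (multi-ring plumes with holes, duplicated vertices, very large
plumes), real-file attribute quirks beyond the documented label set, or
anything about how well HMS plumes proxy ground-level PM2.5. The 2008–2009
density gaps in the archive are likewise not diagnosed; any configured date
range is treated uniformly, with absent days simply counted.

## Problem sizes and checks

The correctness suite compares the full pipeline against the brute-force
oracle on 20+ seeded scenarios of up to 500 points × 30 days — sizes chosen
to keep the whole suite interactive while covering the edge cases that
matter (no plumes, a blanket plume covering every point, nested same-density
plumes, all-three-density overlap, boundary-touching points, concave
plumes). Conservation laws (county→state person-days, series→national
totals) are asserted exactly, as integer arithmetic demands. The national
CenPop2010 row count (220,334 block groups) is checked when the Census file
is reachable.

## Known limitations

Point-per-block-group assignment is all-or-nothing; partial plume coverage
of a block group is invisible. No nighttime smoke exists in HMS at all. The
density→PM2.5 correspondence is approximate and not a concentration
estimate. Planar lon/lat containment slightly distorts plume edges at high
latitudes, and antimeridian-crossing polygons are unsupported. The fetcher
assumes the current archive URL layout (`<year>/GIS/SMOKE/hms_smoke<yyyymmdd>.zip`)
and treats HTTP 404 as "day absent", which conflates a truly missing day
with an archive re-layout.
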