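"""Relational persistence of plants, spikes, images and extracted features.

Two blocks: an uploaded block of five tables (Collection, Plant,
Environment, Spike, Image) describing the collection material, and an
extracted block of six tables (SpikeData, QuadrangleModel, MeanColor,
DominantColor, GLCMTexture, GLRMTexture) keyed by Image and holding the
digital-phenotyping output.  Backed by a single SQLite file with
dialect-neutral DDL; batch import is transactional with row-level
rejection reporting.
"""

from __future__ import annotations

import csv
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import MigrationError, ReferentialError, ValidationError

__all__ = [
    "SpikeDatabase",
    "ImportReport",
    "init_schema",
    "UPLOADED_TABLES",
    "EXTRACTED_TABLES",
    "PLANT_FIELDS",
]

UPLOADED_TABLES = ("Collection", "Plant", "Environment", "Spike", "Image")
EXTRACTED_TABLES = (
    "SpikeData",
    "QuadrangleModel",
    "MeanColor",
    "DominantColor",
    "GLCMTexture",
    "GLRMTexture",
)

#: The 20 Plant columns.  The named ones (vegetation year, accession
#: number, sowing identifier, reproduction number, Q-gene allele, parent
#: information, taxonomy, origin) are fixed; the remainder round out the
#: taxonomic/origin description, and `annex` preserves unmapped manifest
#: columns as JSON text.
PLANT_FIELDS = (
    "plant_id",
    "collection_id",
    "vegetation_year",
    "accession_number",
    "sowing_id",
    "reproduction_number",
    "q_gene_allele",
    "parent_female",
    "parent_male",
    "genus",
    "species",
    "subspecies",
    "variety",
    "botanical_form",
    "ploidy",
    "genome_formula",
    "origin_country",
    "origin_institution",
    "line_name",
    "annex",
)

_SPIKE_FIELDS = (
    "spike_number",
    "length_mm",
    "width_frontal_mm",
    "width_lateral_mm",
    "spike_type",
    "spike_color",
    "grain_count",
    "awn_color",
    "awn_type",
    "glume_pubescence",
    "threshability",
    "rachis_fragility",
    "awn_attachment",
)

_ENVIRONMENT_FIELDS = (
    "sowing_date",
    "harvest_date",
    "location",
    "latitude",
    "longitude",
    "institution_address",
)

_DDL: dict[str, str] = {
    "Collection": """
        CREATE TABLE Collection (
            collection_id INTEGER PRIMARY KEY,
            name TEXT NOT NULL UNIQUE,
            description TEXT
        )""",
    "Plant": """
        CREATE TABLE Plant (
            plant_id INTEGER PRIMARY KEY,
            collection_id INTEGER NOT NULL REFERENCES Collection(collection_id),
            vegetation_year INTEGER,
            accession_number TEXT NOT NULL,
            sowing_id TEXT,
            reproduction_number INTEGER,
            q_gene_allele TEXT,
            parent_female TEXT,
            parent_male TEXT,
            genus TEXT,
            species TEXT,
            subspecies TEXT,
            variety TEXT,
            botanical_form TEXT,
            ploidy TEXT,
            genome_formula TEXT,
            origin_country TEXT,
            origin_institution TEXT,
            line_name TEXT,
            annex TEXT,
            UNIQUE (collection_id, accession_number)
        )""",
    "Environment": """
        CREATE TABLE Environment (
            environment_id INTEGER PRIMARY KEY,
            plant_id INTEGER NOT NULL REFERENCES Plant(plant_id),
            sowing_date TEXT,
            harvest_date TEXT,
            location TEXT,
            latitude REAL,
            longitude REAL,
            institution_address TEXT
        )""",
    "Spike": """
        CREATE TABLE Spike (
            spike_id INTEGER PRIMARY KEY,
            plant_id INTEGER NOT NULL REFERENCES Plant(plant_id),
            spike_number INTEGER NOT NULL,
            length_mm REAL,
            width_frontal_mm REAL,
            width_lateral_mm REAL,
            spike_type TEXT,
            spike_color TEXT,
            grain_count INTEGER,
            awn_color TEXT,
            awn_type TEXT,
            glume_pubescence TEXT,
            threshability TEXT,
            rachis_fragility TEXT,
            awn_attachment TEXT,
            UNIQUE (plant_id, spike_number)
        )""",
    "Image": """
        CREATE TABLE Image (
            image_id INTEGER PRIMARY KEY,
            spike_id INTEGER NOT NULL REFERENCES Spike(spike_id),
            view_number INTEGER NOT NULL,
            acquisition_date TEXT,
            file_path TEXT NOT NULL,
            UNIQUE (spike_id, view_number)
        )""",
    "SpikeData": """
        CREATE TABLE SpikeData (
            image_id INTEGER PRIMARY KEY REFERENCES Image(image_id),
            c_L REAL, c_P REAL, c_S REAL, c_Ci REAL,
            c_Ro REAL, c_So REAL, c_Ru REAL, c_Sa REAL
        )""",
    "QuadrangleModel": """
        CREATE TABLE QuadrangleModel (
            image_id INTEGER PRIMARY KEY REFERENCES Image(image_id),
            q_L REAL, q_W REAL, q_pW REAL, q_a_edge REAL, q_b_edge REAL,
            q_alpha REAL, q_beta REAL, q_gamma REAL,
            q_A REAL, q_P REAL, q_r REAL
        )""",
    "MeanColor": """
        CREATE TABLE MeanColor (
            image_id INTEGER NOT NULL REFERENCES Image(image_id),
            region TEXT NOT NULL CHECK (region IN ('body', 'awn')),
            rgb_R REAL, rgb_G REAL, rgb_B REAL,
            lab_L REAL, lab_a REAL, lab_b REAL,
            hsv_H REAL, hsv_S REAL, hsv_V REAL,
            ycrcb_Y REAL, ycrcb_Cr REAL, ycrcb_Cb REAL,
            PRIMARY KEY (image_id, region)
        )""",
    "DominantColor": """
        CREATE TABLE DominantColor (
            image_id INTEGER NOT NULL REFERENCES Image(image_id),
            region TEXT NOT NULL CHECK (region IN ('body', 'awn')),
            rank INTEGER NOT NULL CHECK (rank IN (1, 2, 3)),
            R REAL, G REAL, B REAL,
            proportion REAL,
            PRIMARY KEY (image_id, region, rank)
        )""",
    "GLCMTexture": """
        CREATE TABLE GLCMTexture (
            image_id INTEGER PRIMARY KEY REFERENCES Image(image_id),
            contrast REAL, dissimilarity REAL, homogeneity REAL,
            ASM REAL, energy REAL, correlation REAL, entropy REAL,
            maximum_probability REAL, cluster_shade REAL,
            cluster_prominence REAL
        )""",
    "GLRMTexture": """
        CREATE TABLE GLRMTexture (
            image_id INTEGER PRIMARY KEY REFERENCES Image(image_id),
            SRE REAL, LRE REAL, GLN REAL, RLN REAL, RP REAL, LGRE REAL
        )""",
}

ALL_TABLES = UPLOADED_TABLES + EXTRACTED_TABLES

# SQLite column names are case-insensitive, so the edge lengths q_a / q_b
# (which collide with area q_A) get distinct SQL names; feature codes are
# restored on export.
_QUAD_TO_SQL = {"q_a": "q_a_edge", "q_b": "q_b_edge"}
_QUAD_FROM_SQL = {v: k for k, v in _QUAD_TO_SQL.items()}

# Same story for mean_B (RGB) vs mean_b (Lab): MeanColor SQL columns are
# namespaced by color space.
_MEANCOLOR_TO_SQL = {
    "mean_R": "rgb_R", "mean_G": "rgb_G", "mean_B": "rgb_B",
    "mean_L": "lab_L", "mean_a": "lab_a", "mean_b": "lab_b",
    "mean_H": "hsv_H", "mean_S": "hsv_S", "mean_V": "hsv_V",
    "mean_Y": "ycrcb_Y", "mean_Cr": "ycrcb_Cr", "mean_Cb": "ycrcb_Cb",
}

_MANIFEST_REQUIRED = ("collection", "accession_number", "spike_number", "view_number", "image_file")
_MANIFEST_PLANT = tuple(
    f for f in PLANT_FIELDS if f not in ("plant_id", "collection_id", "annex", "accession_number")
)
_MANIFEST_SPIKE = tuple(f for f in _SPIKE_FIELDS if f != "spike_number")
_MANIFEST_ENV = _ENVIRONMENT_FIELDS
_MANIFEST_IMAGE = ("acquisition_date",)

_GROUP_COLUMNS = {
    "country_of_origin": "origin_country",
    "variety": "variety",
    "year": "vegetation_year",
}


@dataclass
class ImportReport:
    inserted_plants: int = 0
    inserted_spikes: int = 0
    inserted_images: int = 0
    inserted_rows: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


class SpikeDatabase:
    """Handle over the 11-table SQLite schema."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "SpikeDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # --- schema -----------------------------------------------------------

    def _existing_columns(self, table: str) -> list[str] | None:
        cur = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name=?", (table,)
        )
        if cur.fetchone() is None:
            return None
        return [r[1] for r in self.conn.execute(f"PRAGMA table_info({table})")]

    def init_schema(self) -> None:
        """Create all 11 tables; idempotent, refuses incompatible files."""
        for table, ddl in _DDL.items():
            existing = self._existing_columns(table)
            if existing is None:
                self.conn.execute(ddl)
            else:
                expected = _ddl_columns(ddl)
                if existing != expected:
                    raise MigrationError(
                        f"table {table} exists with columns {existing}, "
                        f"expected {expected}"
                    )
        self.conn.commit()

    def table_names(self) -> list[str]:
        cur = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' "
            "AND name NOT LIKE 'sqlite_%'"
        )
        return [r[0] for r in cur.fetchall()]

    def columns(self, table: str) -> list[str]:
        cols = self._existing_columns(table)
        if cols is None:
            raise ValidationError(f"no such table {table!r}")
        return cols

    # --- batch import -----------------------------------------------------

    def _get_or_create_collection(self, name: str) -> int:
        row = self.conn.execute(
            "SELECT collection_id FROM Collection WHERE name=?", (name,)
        ).fetchone()
        if row:
            return row[0]
        cur = self.conn.execute("INSERT INTO Collection (name) VALUES (?)", (name,))
        return cur.lastrowid

    def batch_import(self, manifest_csv: str | Path, images_dir: str | Path) -> ImportReport:
        """Validate and insert a CSV manifest of plants/spikes/images.

        Each manifest row describes one image.  Rows failing validation
        (missing image file, duplicate (spike, view)) are rejected
        individually; the surviving rows are committed in a single
        transaction.  Unknown manifest columns are preserved in the
        plant's free-text annex rather than dropped.
        """
        images_dir = Path(images_dir)
        with open(manifest_csv, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ValidationError("manifest has no header row")
            missing = [c for c in _MANIFEST_REQUIRED if c not in reader.fieldnames]
            if missing:
                raise ValidationError(f"manifest lacks required columns {missing}")
            known = set(
                _MANIFEST_REQUIRED
                + _MANIFEST_PLANT
                + _MANIFEST_SPIKE
                + _MANIFEST_ENV
                + _MANIFEST_IMAGE
            )
            extra_cols = [c for c in reader.fieldnames if c not in known]
            rows = list(reader)

        report = ImportReport()
        seen_batch: set[tuple[str, str, str, str]] = set()
        try:
            for idx, row in enumerate(rows):
                key = (
                    row["collection"],
                    row["accession_number"],
                    row["spike_number"],
                    row["view_number"],
                )
                if key in seen_batch:
                    report.rejected.append((idx, "duplicate (spike, view) in batch"))
                    continue
                image_path = images_dir / row["image_file"]
                if not image_path.is_file():
                    report.rejected.append((idx, f"missing image file {row['image_file']}"))
                    continue

                collection_id = self._get_or_create_collection(row["collection"])
                plant_id = self._ensure_plant(collection_id, row, extra_cols, report)
                spike_id = self._ensure_spike(plant_id, row, report)
                dup = self.conn.execute(
                    "SELECT image_id FROM Image WHERE spike_id=? AND view_number=?",
                    (spike_id, int(row["view_number"])),
                ).fetchone()
                if dup:
                    report.rejected.append((idx, "duplicate (spike, view) in database"))
                    continue
                self.conn.execute(
                    "INSERT INTO Image (spike_id, view_number, acquisition_date, file_path)"
                    " VALUES (?, ?, ?, ?)",
                    (
                        spike_id,
                        int(row["view_number"]),
                        row.get("acquisition_date"),
                        str(Path(row["image_file"])),
                    ),
                )
                seen_batch.add(key)
                report.inserted_images += 1
                report.inserted_rows += 1
        except Exception:
            self.conn.rollback()
            raise
        self.conn.commit()
        return report

    def _ensure_plant(
        self, collection_id: int, row: dict, extra_cols: list[str], report: ImportReport
    ) -> int:
        found = self.conn.execute(
            "SELECT plant_id FROM Plant WHERE collection_id=? AND accession_number=?",
            (collection_id, row["accession_number"]),
        ).fetchone()
        if found:
            return found[0]
        values = {f: row.get(f) or None for f in _MANIFEST_PLANT}
        annex = {c: row[c] for c in extra_cols if row.get(c)}
        cols = ["collection_id", "accession_number"] + list(values) + ["annex"]
        vals = [collection_id, row["accession_number"]] + list(values.values()) + [
            json.dumps(annex) if annex else None
        ]
        cur = self.conn.execute(
            f"INSERT INTO Plant ({', '.join(cols)}) VALUES ({', '.join('?' * len(vals))})",
            vals,
        )
        plant_id = cur.lastrowid
        env_vals = {f: row.get(f) or None for f in _MANIFEST_ENV}
        if any(v is not None for v in env_vals.values()):
            cols = ["plant_id"] + list(env_vals)
            vals = [plant_id] + list(env_vals.values())
            self.conn.execute(
                f"INSERT INTO Environment ({', '.join(cols)}) "
                f"VALUES ({', '.join('?' * len(vals))})",
                vals,
            )
        report.inserted_plants += 1
        return plant_id

    def _ensure_spike(self, plant_id: int, row: dict, report: ImportReport) -> int:
        spike_number = int(row["spike_number"])
        found = self.conn.execute(
            "SELECT spike_id FROM Spike WHERE plant_id=? AND spike_number=?",
            (plant_id, spike_number),
        ).fetchone()
        if found:
            return found[0]
        values = {f: row.get(f) or None for f in _MANIFEST_SPIKE}
        cols = ["plant_id", "spike_number"] + list(values)
        vals = [plant_id, spike_number] + list(values.values())
        cur = self.conn.execute(
            f"INSERT INTO Spike ({', '.join(cols)}) VALUES ({', '.join('?' * len(vals))})",
            vals,
        )
        report.inserted_spikes += 1
        return cur.lastrowid

    # --- extracted features ----------------------------------------------

    def _require_image(self, image_id: int) -> None:
        row = self.conn.execute(
            "SELECT image_id FROM Image WHERE image_id=?", (image_id,)
        ).fetchone()
        if row is None:
            raise ReferentialError(f"no Image row with id {image_id}")

    def store_features(self, image_id: int, records: dict) -> None:
        """Persist extracted-feature records for one image.

        ``records`` maps table-intent keys to feature objects/dicts:
        ``outline`` (SpikeData), ``quad`` (QuadrangleModel),
        ``mean_color`` ({region: MeanColorFeatures}),
        ``dominant`` ({region: DominantColors}), ``glcm``, ``glrm``.
        """
        self._require_image(image_id)
        try:
            if "outline" in records:
                d = _values(records["outline"])
                self._upsert("SpikeData", {"image_id": image_id, **d})
            if "quad" in records:
                d = _values(records["quad"])
                d.pop("clamped", None)
                d = {_QUAD_TO_SQL.get(k, k): v for k, v in d.items()}
                self._upsert("QuadrangleModel", {"image_id": image_id, **d})
            for region, rec in (records.get("mean_color") or {}).items():
                d = _values(rec)
                d = {
                    _MEANCOLOR_TO_SQL[k]: v
                    for k, v in d.items()
                    if k in _MEANCOLOR_TO_SQL
                }
                self._upsert("MeanColor", {"image_id": image_id, "region": region, **d})
            for region, rec in (records.get("dominant") or {}).items():
                for rank in range(3):
                    self._upsert(
                        "DominantColor",
                        {
                            "image_id": image_id,
                            "region": region,
                            "rank": rank + 1,
                            "R": float(rec.centroids[rank][0]),
                            "G": float(rec.centroids[rank][1]),
                            "B": float(rec.centroids[rank][2]),
                            "proportion": float(rec.proportions[rank]),
                        },
                    )
            if "glcm" in records:
                d = _values(records["glcm"])
                d.pop("constant_region", None)
                self._upsert("GLCMTexture", {"image_id": image_id, **d})
            if "glrm" in records:
                d = _values(records["glrm"])
                d.pop("constant_region", None)
                self._upsert("GLRMTexture", {"image_id": image_id, **d})
        except Exception:
            self.conn.rollback()
            raise
        self.conn.commit()

    def _upsert(self, table: str, values: dict) -> None:
        cols = list(values)
        sql = (
            f"INSERT OR REPLACE INTO {table} ({', '.join(cols)}) "
            f"VALUES ({', '.join('?' * len(cols))})"
        )
        self.conn.execute(sql, [values[c] for c in cols])

    def export_features(
        self, view_number: int | None = None, out_dir: str | Path | None = None
    ) -> dict[str, pd.DataFrame]:
        """Extracted-block tables as DataFrames (optionally filtered by
        view), round-tripping stored values at full precision; written
        as a CSV bundle when ``out_dir`` is given."""
        frames: dict[str, pd.DataFrame] = {}
        for table in EXTRACTED_TABLES:
            sql = f"SELECT t.* FROM {table} t"
            params: tuple = ()
            if view_number is not None:
                sql += " JOIN Image i ON i.image_id = t.image_id WHERE i.view_number = ?"
                params = (view_number,)
            frame = pd.read_sql_query(sql, self.conn, params=params)
            if table == "QuadrangleModel":
                frame = frame.rename(columns=_QUAD_FROM_SQL)
            frames[table] = frame
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            for table, frame in frames.items():
                frame.to_csv(out_dir / f"{table}.csv", index=False, float_format="%.17g")
            meta = {
                "tables": {t: len(f) for t, f in frames.items()},
                "view_number": view_number,
            }
            (out_dir / "export.json").write_text(json.dumps(meta, indent=2))
        return frames

    # --- summaries --------------------------------------------------------

    def summary_stats(
        self, group_by: str, top_k: int | None = None
    ) -> list[tuple[object, int]]:
        """Frequency table of plants per category, descending."""
        if group_by not in _GROUP_COLUMNS:
            raise ValidationError(
                f"unknown grouping field {group_by!r}; "
                f"choose from {sorted(_GROUP_COLUMNS)}"
            )
        col = _GROUP_COLUMNS[group_by]
        cur = self.conn.execute(
            f"SELECT {col}, COUNT(*) AS n FROM Plant WHERE {col} IS NOT NULL "
            f"GROUP BY {col} ORDER BY n DESC, {col}"
        )
        rows = [(r[0], r[1]) for r in cur.fetchall()]
        return rows[:top_k] if top_k is not None else rows


def _ddl_columns(ddl: str) -> list[str]:
    body = ddl[ddl.index("(") + 1 : ddl.rindex(")")]
    cols = []
    depth = 0
    for part in _split_top_level(body):
        name = part.split()[0]
        if name.upper() in ("PRIMARY", "UNIQUE", "FOREIGN", "CHECK"):
            continue
        cols.append(name)
    return cols


def _split_top_level(text: str) -> list[str]:
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    if cur:
        parts.append("".join(cur).strip())
    return [p for p in parts if p]


def _values(record) -> dict:
    if hasattr(record, "as_dict"):
        d = dict(record.__dict__) if hasattr(record, "__dict__") else {}
        # prefer dataclass fields over as_dict-prefixed names
        import dataclasses as _dc

        if _dc.is_dataclass(record):
            d = _dc.asdict(record)
        d.pop("region", None)
        return d
    return dict(record)


def init_schema(db_path: str | Path) -> SpikeDatabase:
    """Open (creating if needed) a database file with the full schema."""
    path = Path(db_path)
    if path.exists() and not path.is_file():
        raise ValidationError(f"{path} is not a file")
    try:
        db = SpikeDatabase(path)
        db.init_schema()
    except sqlite3.OperationalError as exc:
        raise OSError(f"cannot initialize database at {path}: {exc}") from exc
    return db
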