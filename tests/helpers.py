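"""Shared builders for test records."""

from nutriwarn.types import NutrientPanel, ProductRecord, ScopeFlags


def make_record(
    product_id="p1",
    period="T3",
    year=2020,
    group="snacks",
    basis="solid",
    energy=100.0,
    sugars=5.0,
    satfat=1.0,
    totalfat=None,
    sodium=100.0,
    serving=50.0,
    scope=(True, True, True),
    regulated=True,
    factor=None,
    requires_recon=False,
    family=None,
    market=None,
) -> ProductRecord:
    return ProductRecord(
        product_id=product_id,
        period=period,
        collection_year=year,
        group=group,
        basis=basis,
        panel=NutrientPanel(
            energy_kcal=energy,
            sugars_g=sugars,
            satfat_g=satfat,
            totalfat_g=totalfat,
            sodium_mg=sodium,
            serving_size=serving,
        ),
        scope=None if scope is None else ScopeFlags(*scope),
        regulated_category=regulated,
        requires_reconstitution=requires_recon,
        reconstitution_factor=factor,
        brand_family=family,
        market_group=market,
    )
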