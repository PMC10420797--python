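# Default melatonin-containing product table (illustrative).
# Serving masses are typical household portions; melatonin contents are
# order-of-magnitude values from the food-melatonin literature, which vary
# widely between cultivars and studies. Analyses should supply their own
# audited table; this default exists so the pipeline runs out of the box.
# units: ng_per_g (melatonin_content is ng per gram of product).
product_id,name,serving_mass,melatonin_content,units
cherry,tart cherries,150,13.5,ng_per_g
walnut,walnuts,30,3.5,ng_per_g
tomato,tomatoes,120,0.25,ng_per_g
banana,bananas,120,0.3,ng_per_g
oats,oat porridge,200,0.9,ng_per_g
rice,rice,180,0.6,ng_per_g
milk,cow milk,200,0.014,ng_per_g
egg,eggs,60,1.5,ng_per_g
grape,grapes,150,0.5,ng_per_g
strawberry,strawberries,150,0.14,ng_per_g
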