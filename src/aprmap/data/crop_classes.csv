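source_code,source_label,target_class
211,Common Wheat,Wheat
212,Durum Wheat,Wheat
213,Barley,Other
214,Rye,Other
215,Oats,Other
216,Maize,Corn
217,Rice,Rice
218,Triticale,Other
219,Other cereals,Other
221,Potatoes,VegFru
222,Sugar beets,Other
223,Other root crops,VegFru
230,Other non-permanent industrial crops,EXCLUDED
231,Sunflower,Other
232,Rape and turnip rape,VegFru
233,Soya,Soybean
240,Dry pulses,VegFru
250,Fodder crops,EXCLUDED
290,Bare arable lands,EXCLUDED
350,Orchards and grapes,OrcGra
510,Pastures,PasHay
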