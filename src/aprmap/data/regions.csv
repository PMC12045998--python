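country,region
Bulgaria,SEU
Greece,SEU
Spain,SEU
France,SEU
Italy,SEU
Cyprus,SEU
Malta,SEU
Portugal,SEU
Belgium,CEU
Czech Republic,CEU
Germany,CEU
Ireland,CEU
Luxembourg,CEU
Hungary,CEU
Netherlands,CEU
Austria,CEU
Poland,CEU
Romania,CEU
Slovenia,CEU
Slovakia,CEU
United Kingdom,CEU
Denmark,NEU
Estonia,NEU
Latvia,NEU
Lithuania,NEU
Finland,NEU
Sweden,NEU
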