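# Zhejiang Province prefecture-level contiguity (11 cities), read from the
# public administrative map.  Zhoushan is an island prefecture joined to the
# mainland only through Ningbo.
# regions: Hangzhou,Ningbo,Wenzhou,Jiaxing,Huzhou,Shaoxing,Jinhua,Quzhou,Zhoushan,Taizhou,Lishui
Hangzhou Huzhou
Hangzhou Jiaxing
Hangzhou Shaoxing
Hangzhou Jinhua
Hangzhou Quzhou
Jiaxing Huzhou
Shaoxing Ningbo
Shaoxing Jinhua
Shaoxing Taizhou
Ningbo Taizhou
Ningbo Zhoushan
Jinhua Quzhou
Jinhua Lishui
Jinhua Taizhou
Quzhou Lishui
Lishui Taizhou
Lishui Wenzhou
Taizhou Wenzhou
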