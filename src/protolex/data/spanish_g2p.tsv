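pattern	left_context	right_context	phonemes	priority	dialect_var
ch			tʃ	1
ll			ʝ	1
rr			r	1
qu		eiéí	k	1
gu		eiéí	g	1
gü		ei	g w	1
a			a	1
á			a	1
e			e	1
é			e	1
i			i	1
í			i	1
o			o	1
ó			o	1
u			u	1
ú			u	1
ü			u	1
b			b	1
c		eiéí	s	2	szeta
c			k	1
d			d	1
f			f	1
g		eiéí	x	2
g			g	1
h			-	1
j			x	1
k			k	1
l			l	1
m			m	1
n			n	1
ñ			ɲ	1
p			p	1
q			k	1
r	#		r	2
r	lns		r	2
r			ɾ	1
s			s	1
t			t	1
v			b	1
w			w	1
x			k s	1
y		#	i	2
y			ʝ	1
z			s	1	szeta
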