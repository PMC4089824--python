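character	description
1	Shape of union between clypeus and frons: (0) clypeus slightly depressed, weak fronto-clypeal suture; (1) clypeus strongly depressed, evident fronto-clypeal suture
2	Length of antennae (male): (0) short, slightly over posterior margin of pronotum; (1) long, clearly surpassing posterior margin of pronotum
3	Shape of antennae: (0) filiform; (1) submoniliform
4	Length of third antennomere: (0) longer than apical antennomeres; (1) shorter than or as long as apical antennomeres
5	Size of last antennomere (female): (0) almost as long as wide or wider than long; (1) 2.5 or more times as long as wide; (2) 1.5-2 times as long as wide
6	Head width: (0) 1.5 times width of intraocular space; (1) less than 1.5 times width of intraocular space
7	Length of inner edge of maxillary palp (male): (0) 1-1.5 times length of posterior edge; (1) 1.6-2.5 times length of posterior edge; (2) 2.6-2.9 times length of posterior edge
8	Pronotum disk surface: (0) gibbous; (1) not gibbous
9	Density of pronotum punctures: (0) very dense or confluent; (1) moderately dense; (2) sparse
10	Depth of pronotum punctation: (0) deep (more than 20 μm); (1) medium (10-20 μm); (2) shallow (less than 10 μm)
11	Setae of head and pronotum (observed at a magnification up to 140X): (0) present; (1) not evident
12	Width of lateral carinae of pronotum: (0) lateral carinae 2-5 times width of anterior carinae; (1) lateral carinae less than 2 times width of anterior carina
13	Shape of anterior angles of pronotum: (0) acute; (1) blunt or slightly acute; (2) straight
14	Lateral sides of pronotum: (0) with crenate carinae; (1) with smooth carinae; (2) without conspicuous carinae
15	Shape of posterior angles of pronotum: (0) straight; (1) acute; (2) blunt; (3) obtuse
16	Projection of posterior angles of pronotum: (0) strong; (1) weak
17	Posterior margin of pronotum: (0) convex; (1) straight; (2) bisinuate
18	Pronotum shape: (0) rectangular (its width 1.5 times or more its length); (1) almost square (its width less than 1.5 its length)
19	Propleura texture: (0) strongly rugose or punctated; (1) smooth or slightly rugose or punctated
20	Elytra shape in lateral view: (0) strongly arcuate; (1) slightly arcuate; (2) more evident towards the middle and posteriorly
21	Pronotum tegument: (0) smooth; (1) chagrined
22	Elytra punctures: (0) in grooves; (1) in rows
23	Shape of elytral interstriae: (0) convex; (1) flat; (2) acute
24	Elytral tegument: (0) lustrous; (1) dull
25	Metathoracic wings: (0) brachypterous or not evident; (1) fully developed
26	Size of recurrent cell: (0) reduced (due to the approximation of the radial cross-vein to the recurrent radius); (1) wide (due to the separation of the radial cross-vein to the recurrent radius)
27	Shape of prosternal process apex in ventral view: (0) strongly projected; (1) weakly, or not projected
28	Shape of prosternal process apex in lateral view: (0) straight; (1) declivous
29	Density of leg punctures: (0) femur punctures sparser than tibia punctures; (1) density of femur and tibia punctures similar
30	Shape of third tarsomere: (0) lobate; (1) not lobate
31	Size of fourth tarsomere: (0) shorter than third tarsomere; (1) as long as third tarsomere
32	Density of punctures and pubescence of abdominal ventrites (male): (0) high towards middle of ventrites 1-3; (1) homogeneous on ventrites 1-5; (2) high towards middle of ventrites 1-5
33	Shape of inner sternite VIII (female): (0) blunt and narrow; (1) trapeziform or blunt and wide
34	Arms of spiculum ventrale (female): (0) evident; (1) not evident
35	Shape of distal end of stalk of spiculum ventrale (female): (0) round or oval and dilated; (1) round but not dilated
36	Length/width ratio of gonostyles (female): (0) length twice or more its width; (1) length less than twice its width
37	Relative length of coxites (female): (0) 8 or more times gonostyle length; (1) less than 8 times gonostyle length
38	Shape of gonostyles (female): (0) apex as wide as base; (1) with apex wider than base
39	Relative length of paraproct (female): (0) three or more times coxite length; (1) two times coxite length; (2) as long as coxites; (3) less than coxite length
40	Shape of vagina (female): (0) infundibular or sacciform, curved or not at the apex (i.e., at the connection with the spermatheca or common duct); (1) sacciform and strongly narrowed and curved before the apex
41	Number of spermathecal tubes: (0) one; (1) more than one
42	Spermathecal tubes structure: (0) branched near the base; (1) not branched, branched at the base (looking like a fascicule of tubes), or branched far from the base
43	Spermathecal tubes arrangement: (0) near to each other; (1) distant from each other
44	Common duct: (0) present; (1) absent
45	Length of common duct of spermatheca and accessory gland: (0) long; (1) short; (2) intermediate
46	Position of common duct (female): (0) apical to vagina; (1) anterior to vagina apex
47	Width of spermathecal tube(s) (female): (0) increases distally; (1) homogeneous width or gradually decreasing
48	Texture of spermathecal tubes: (0) smooth; (1) annulate
49	Position of accessory gland: (0) emerging directly from the vagina, far from the spermatheca; (1) in the common duct; (2) terminal to the spermathecal tubes and common duct
50	Arrangement of pleural rods of gastral spicula (male): (0) close towards the middle of their length; (1) close towards the proximal third; (2) close only at the end
51	Shape of pleural rods of gastral spicula (male): (0) straight of slightly curved; (1) strongly curved
52	Depth of notch of eighth sternite (male) measured as the ratio of sternite length (SL) and notch length (NL): (0) deep (SL/NL <3); (1) shallow (SL/NL >3); (2) without notch
53	Width of notch of eighth sternite (male): (0) wide; (1) narrow
54	Shape of lobes of eighth sternite (male): (0) notably and anteriorly wide; (1) narrow and acute or slightly blunt
55	Relative length of basal piece (male): (0) three or more times the length of parameres; (1) less than three times the length of parameres
56	Shape of parameres in lateral view (male): (0) sinuate; (1) straight or slightly curved
57	Setae on parameres (male): (0) present; (1) not evident (observed at a magnification up to 140X)
58	Distribution of evident setae on parameres (male): (0) covering apical half of parameres; (1) covering more than two thirds of parameres
59	Sides of parameres in ventral view (male): (0) convergent to the apex, with a fusiform space in between; (1) not convergent
60	Constriction of the apex of parameres (male): (0) present; (1) absent
61	Constriction of the apex of parameres (male): (0) strong; (1) weak
62	Shape of the apex of parameres (male): (0) blunt or straight; (1) acute; (2) fan shaped
63	Apical projection of parameres in ventral direction (lateral and ventral view): (0) present; (1) absent
64	Apical compression of parameres view laterally as a dorsal or dorso-ventral projection or keel: (0) present; (1) not evident (observed at a magnification up to 140X)
65	Width of parameres (male) at the middle: (0) narrower than basal piece; (1) as wide as basal piece
66	Shape of apex of median lobe (male): (0) blunt or with an inconspicuous notch; (1) lobate; (2) constricted
67	Shape of anterior part of basal piece (male): (0) projected, basal piece “J” shaped; (1) not projected; (2) projected, basal piece “C” shaped
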