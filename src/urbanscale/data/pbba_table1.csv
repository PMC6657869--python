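# Transcription of the published per-species summary table (Second
# Pennsylvania Breeding Bird Atlas analysis): model-averaged urbanization
# effect size +/- SE at each species' scale of effect. Transcribed values,
# not computed by this package.
common_name,scientific_name,n,effect,se,scale_km
Canada Warbler,Cardellina canadensis,7010,-1.49,0.50,1
Black-throated Blue Warbler,Setophaga caerulescens,9222,-1.19,0.21,1
Winter Wren,Troglodytes hiemalis,5851,-1.16,0.27,1
Louisiana Waterthrush,Parkesia motacilla,13732,-1.12,0.18,0.5
Least Flycatcher,Empidonax minimus,10473,-1.09,0.21,1
Hermit Thrush,Catharus guttatus,11059,-1.06,0.10,2
Pine Warbler,Setophaga pinus,5849,-0.95,0.31,16
Magnolia Warbler,Setophaga magnolia,8610,-0.91,0.13,1
Northern Parula,Setophaga americana,8077,-0.90,0.20,1
Yellow-bellied Sapsucker,Sphyrapicus varius,6440,-0.87,0.12,8
Mourning Warbler,Geothlypis philadephia,2909,-0.86,0.40,0.5
Worm-eating Warbler,Helmitheros vermivorum,3047,-0.82,0.32,0.2
Dark-eyed Junco,Junco hyemalis,9295,-0.81,0.10,8
Brown Creeper,Certhia americana,3279,-0.78,0.23,0.2
Blackburnian Warbler,Setophaga fusca,9241,-0.72,0.10,1
Golden-winged Warbler,Vermivora chrysoptera,2010,-0.70,0.32,2
Black-throated Green Warbler,Setophaga virens,11842,-0.68,0.07,1
Common Raven,Corvus corax,13101,-0.66,0.16,2
Ovenbird,Seiurus aurocapilla,13701,-0.62,0.05,16
Veery,Catharus fuscescens,13071,-0.61,0.06,0.2
Golden-crowned Kinglet,Regulus satrapa,3701,-0.58,0.31,2
Yellow-throated Vireo,Vireo flavifrons,9641,-0.56,0.14,6
Chestnut-sided Warbler,Setophaga pensylvanica,13494,-0.54,0.06,1
Hooded Warbler,Setophaga citrina,6050,-0.54,0.13,0.2
Swamp Sparrow,Melospiza georgiana,7987,-0.52,0.18,16
Great Crested Flycatcher,Myiarchus crinitus,13748,-0.48,0.10,16
Blue-headed Vireo,Vireo solitarius,11593,-0.44,0.08,1
Cerulean Warbler,Setophaga cerulea,6782,-0.44,0.14,6
Acadian Flycatcher,Empidonax virescens,13761,-0.39,0.06,0.2
Scarlet Tanager,Piranga olivacea,7540,-0.34,0.04,0.2
Blue-gray Gnatcatcher,Polioptila caerulea,10547,-0.32,0.08,0.5
Rose-breasted Grosbeak,Pheucticus ludovicianus,11491,-0.31,0.06,0.5
Yellow-billed Cuckoo,Coccyzus americanus,16313,-0.29,0.06,1
American Redstart,Setophaga ruticilla,16208,-0.28,0.04,0.2
Common Yellowthroat,Geothlypis trichas,16407,-0.26,0.03,0.2
Eastern Wood-Pewee,Contopus virens,16407,-0.24,0.03,0.2
Pileated Woodpecker,Dryocopus pileatus,15378,-0.24,0.07,6
Black-and-white Warbler,Mniotilta varia,7204,-0.20,0.07,0.2
Red-eyed Vireo,Vireo olivaceus,11682,-0.19,0.02,0.5
Hairy Woodpecker,Picoides villosus,16407,-0.18,0.07,0.2
Cedar Waxwing,Bombycilla cedrorum,13776,-0.13,0.06,16
Tree Swallow,Tachycineta bicolor,16144,-0.12,0.14,2
Ruby-throated Hummingbird,Archilochus colubris,15391,-0.06,0.06,6
Prairie Warbler,Setophaga discolor,8658,-0.03,0.08,0.2
Red-breasted Nuthatch,Sitta canadensis,3743,0.01,0.06,0.5
Purple Finch,Haemorhous purpureus,10288,0.02,0.05,10
Black-capped Chickadee,Poecile atricapillus,14186,0.03,0.03,10
White-breasted Nuthatch,Sitta carolinensis,15231,0.03,0.03,2
Indigo Bunting,Passerina cyanea,15085,0.08,0.02,8
Eastern Phoebe,Sayornis phoebe,13776,0.09,0.09,16
Yellow-throated Warbler,Setophaga dominica,1150,0.13,0.34,4
Chipping Sparrow,Spizella passerina,16407,0.17,0.02,0.2
Wood Thrush,Hylocichla mustelina,14737,0.19,0.04,10
American Crow,Corvus brachyrhynchos,13776,0.22,0.05,16
Tufted Titmouse,Baeolophus bicolor,13776,0.25,0.04,16
Northern Flicker,Colaptes auratus,13776,0.45,0.08,16
Kentucky Warbler,Geothlypis formosa,3525,0.49,0.47,12
Eastern Towhee,Pipilo erythrophthalmus,13776,0.74,0.06,16
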