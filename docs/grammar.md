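# DSL grammars (EBNF)

Both languages are line-oriented: one statement per line, comments from
`//` or `#` to end of line, blank lines ignored.

## Shared expression grammar

```ebnf
expr      = or_expr ;
or_expr   = and_expr , { "or" , and_expr } ;
and_expr  = not_expr , { "and" , not_expr } ;
not_expr  = "not" , not_expr | cmp_expr ;
cmp_expr  = add_expr , [ cmp_op , add_expr ] ;
cmp_op    = "<" | "<=" | ">" | ">=" | "==" | "!=" ;
add_expr  = mul_expr , { ( "+" | "-" ) , mul_expr } ;
mul_expr  = unary , { ( "*" | "/" ) , unary } ;
unary     = [ "-" | "+" ] , power ;
power     = atom , [ "^" , unary ] ;            (* right-associative *)
atom      = number | identifier | "time" | boolean
          | function , "(" , [ expr , { "," , expr } ] , ")"
          | "(" , expr , ")" ;
function  = "exp" | "ln" | "log" | "log10" | "pow" | "sqrt" | "abs"
          | "piecewise" ;
boolean   = "true" | "false" ;
```

`log` is an alias of `log10`; `ln` is the natural logarithm; `pow(a, b)`
is canonicalized to `a^b`.  `piecewise(v1, c1, v2, c2, ..., [otherwise])`
uses SBML semantics.

## Model language

```ebnf
model_doc   = [ "model" , id ] , { statement } , [ "end" ] ;
statement   = compartment_decl | species_decl | reaction | value_assign
            | init_assign | assignment_rule | rate_rule | event | sbo ;

compartment_decl = "compartment" , comp_item , { "," , comp_item } ;
comp_item        = id , [ "=" , number ] ;

species_decl = "species" , sp_item , { "," , sp_item } ;
sp_item      = [ "$" ] , id , [ "in" , id ] , [ "=" , number ] ;

reaction    = [ id , ":" ] , side , arrow , side , ";" , expr ;
arrow       = "=>"                  (* irreversible *)
            | "->" ;                (* reversible *)
side        = [ sp_ref , { "+" , sp_ref } ] ;
sp_ref      = [ integer ] , [ "$" ] , id ;

value_assign    = [ "$" ] , id , "=" , number ;
init_assign     = id , "=" , expr ;              (* non-literal right side *)
assignment_rule = id , ":=" , expr ;
rate_rule       = id , "'" , "=" , expr ;

event = [ id , ":" ] , "at" , expr , ":" ,
        id , "=" , expr , { "," , id , "=" , expr } ;

sbo   = id , ".sboTerm" , "=" , "SBO:" , 7 * digit ;
```

A `$` prefix anywhere marks the species as a boundary species.  An
identifier used only inside rate laws is implicitly created as a parameter
with value 0 (a warning is emitted).  If no compartment is declared,
`default_compartment` of size 1 is injected.

## Simulation language

```ebnf
sim_doc   = { statement } ;
statement = model_ref | simulation | property | task | repeat
          | plot | report ;

model_ref  = id , "=" , "model" , source ,
             [ "with" , change , { "," , change } ] ;
source     = quoted_string | id ;                (* model block id or path *)
change     = id , "=" , number ;

simulation = id , "=" , "simulate" ,
             ( "uniform" , "(" , number , "," , number , "," , integer , ")"
             | "uniform_stochastic" , "(" , number , "," , number , "," ,
               integer , ")"
             | "steadystate" ) ;

property   = id , "." , prop_name , "=" , prop_value ;
prop_name  = "algorithm" | "variable_step_size" | "relative_tolerance"
           | "absolute_tolerance" | "seed" ;

task   = id , "=" , "run" , id , "on" , id ;
repeat = id , "=" , "repeat" , id , "for" , id , "in" , range ,
         [ "," , "reset=true" ] ;
range  = "uniform" , "(" , number , "," , number , "," , integer , ")"
       | "[" , number , { "," , number } , "]" ;

plot   = "plot" , [ quoted_string ] , curve , { "," , curve } ;
curve  = operand , "vs" , operand | operand ;    (* bare operand reuses x *)
report = "report" , [ quoted_string ] , operand , { "," , operand } ;
operand = expr ;      (* symbols may be task-qualified: task.variable *)
```

`simulate uniform(t0, tEnd, n)` produces `n + 1` output rows (`n`
intervals).  Algorithm keywords: `lsoda` (default), `cvode`, `gillespie`,
`rk4`.  Unqualified variables in plot/report operands are expanded over
every task defined so far, one curve/column per task.
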